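"""Shared sequence record types and on-disk formats.

The pipeline touches plain-text formats only: FASTA (nucleotide and
protein), aligned FASTA for MSAs, GFF3 for predicted genes, Newick for
trees, TSV/JSON for reports.  Internal coordinates are 0-based half-open;
every on-disk report uses the 1-based inclusive convention of its format.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY" + "X*")

FASTA_WIDTH = 60


class FastaFormatError(ValueError):
    """Raised when a FASTA file violates the expected syntax or alphabet."""


@dataclass
class Contig:
    """A nucleotide record entering the pipeline (an assembled contig)."""

    id: str
    seq: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        self.seq = self.seq.upper()
        if len(self.seq) < 1:
            raise ValueError(f"contig {self.id}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(f"contig {self.id}: illegal characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ProteinRecord:
    """An ungapped amino-acid sequence."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValueError(f"protein {self.id}: empty sequence")
        if "-" in self.residues:
            raise ValueError(f"protein {self.id}: gap characters not allowed")
        bad = set(self.residues) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(f"protein {self.id}: illegal characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Msa:
    """A multiple alignment: ordered (id, gapped row) pairs of equal length."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("MSA must have at least one row")
        ncol = len(self.rows[0][1])
        if ncol < 1:
            raise ValueError("MSA must have at least one column")
        for rid, row in self.rows:
            if len(row) != ncol:
                raise ValueError(f"MSA row {rid}: length {len(row)} != {ncol}")

    @property
    def ncol(self) -> int:
        return len(self.rows[0][1])

    @property
    def nrow(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def degapped(self) -> list[ProteinRecord]:
        return [ProteinRecord(rid, row.replace("-", "")) for rid, row in self.rows]


def read_fasta(path: str | Path, alphabet: Literal["dna", "protein"]):
    """Read a FASTA file into Contig or ProteinRecord objects.

    Sequences are uppercased and validated against the declared alphabet;
    duplicate or empty ids and illegal characters raise FastaFormatError
    naming the offending record.
    """
    path = Path(path)
    allowed = DNA_ALPHABET if alphabet == "dna" else PROTEIN_ALPHABET
    records = []
    seen: set[str] = set()
    with open(path) as fh:
        for ordinal, rec in enumerate(SeqIO.parse(fh, "fasta"), start=1):
            seq = str(rec.seq).upper()
            if not rec.id:
                raise FastaFormatError(f"{path}: record {ordinal}: empty id")
            if rec.id in seen:
                raise FastaFormatError(
                    f"{path}: record {ordinal}: duplicate id {rec.id!r}"
                )
            seen.add(rec.id)
            if not seq:
                raise FastaFormatError(
                    f"{path}: record {ordinal} ({rec.id}): empty sequence"
                )
            bad = set(seq) - allowed
            if bad:
                raise FastaFormatError(
                    f"{path}: record {ordinal} ({rec.id}): illegal "
                    f"{alphabet} characters {sorted(bad)}"
                )
            if alphabet == "dna":
                records.append(Contig(rec.id, seq, source=str(path)))
            else:
                records.append(ProteinRecord(rec.id, seq))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def _wrap(seq: str) -> str:
    return "\n".join(seq[i : i + FASTA_WIDTH] for i in range(0, len(seq), FASTA_WIDTH))


def write_fasta(records: Iterable[Contig | ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            seq = rec.seq if isinstance(rec, Contig) else rec.residues
            fh.write(f">{rec.id}\n{_wrap(seq)}\n")


def read_msa_fasta(path: str | Path) -> Msa:
    """Read an aligned (gapped) protein FASTA into an Msa."""
    rows = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            rows.append((rec.id, str(rec.seq).upper()))
    return Msa(rows)


def write_msa_fasta(msa: Msa, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row in msa.rows:
            fh.write(f">{rid}\n{_wrap(row)}\n")


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(orfs, path: str | Path, source: str = "fhalmine") -> None:
    """Write predicted ORFs as GFF3 CDS features.

    Internal 0-based half-open coordinates become 1-based inclusive; the
    partial-gene flags travel in the attribute column.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, orf in enumerate(orfs, start=1):
            if orf.end <= orf.start:
                raise ValueError(f"orf {i}: end {orf.end} <= start {orf.start}")
            attrs = (
                f"ID=orf{i};has_start={str(orf.has_start).lower()};"
                f"has_stop={str(orf.has_stop).lower()};frame={orf.frame}"
            )
            fh.write(
                "\t".join(
                    [
                        orf.contig_id,
                        source,
                        "CDS",
                        str(orf.start + 1),
                        str(orf.end),
                        ".",
                        orf.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[dict]:
    """Parse the GFF3 written by write_gff3 back into plain dicts.

    Used for round-trip checks and report ingestion; not a general GFF3
    reader.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: expected 9 GFF3 columns, got {len(cols)}")
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if kv)
            out.append(
                {
                    "contig_id": cols[0],
                    "type": cols[2],
                    "start": int(cols[3]) - 1,
                    "end": int(cols[4]),
                    "strand": cols[6],
                    "has_start": attrs.get("has_start") == "true",
                    "has_stop": attrs.get("has_stop") == "true",
                    "frame": int(attrs.get("frame", 0)),
                }
            )
    return out


# ---------------------------------------------------------------------------
# Newick

_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.|/+-]+$")


def _quote_label(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def newick_string(tree) -> str:
    """Serialize a PhyloTree (see fhalmine.phylo) to Newick.

    Branch lengths to six decimals; integer bootstrap supports as internal
    node labels; labels with unsafe characters are single-quoted.
    """

    def render(node) -> str:
        if node.is_leaf():
            if not node.name:
                raise ValueError("unnamed leaf in tree")
            s = _quote_label(node.name)
        else:
            inner = ",".join(render(c) for c in node.children)
            label = "" if node.support is None else str(int(node.support))
            s = f"({inner}){label}"
        if node.length is not None:
            s += f":{node.length:.6f}"
        return s

    return render(tree.root) + ";"


def write_newick(tree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(tree) + "\n")
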