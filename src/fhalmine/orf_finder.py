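"""Six-frame ORF prediction and translation on metagenomic contigs.

This is the gene-prediction stage of the mining pipeline, kept deliberately
simple: every maximal start-to-stop span in each of the six reading frames
is reported, and spans that run off a contig edge are emitted as *partial*
genes (missing start and/or stop) so that the downstream completeness
filter — not the gene finder — decides the complete/incomplete split.

Coordinates are 0-based half-open on the forward strand of the contig; the
span includes the stop codon when one is present.  Codons containing 'N'
translate to 'X' and never act as start or stop codons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from Bio.Data import CodonTable

from .seq_io import Contig, ProteinRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DEFAULT_START_CODONS = frozenset({"ATG"})
EXTENDED_START_CODONS = frozenset({"ATG", "GTG", "TTG"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _codon_table(table: int) -> dict[str, str]:
    tbl = CodonTable.unambiguous_dna_by_id[table]
    out = dict(tbl.forward_table)
    for stop in tbl.stop_codons:
        out[stop] = "*"
    return out

# The bacterial/archaeal code (NCBI table 11) is the pipeline default.
_TABLE_CACHE: dict[int, dict[str, str]] = {}


def translate(nt_seq: str, table: int = 11, start_to_met: bool = False) -> str:
    """Translate a codon-multiple nucleotide string.

    A trailing stop codon is dropped; internal stops are preserved as '*'
    (flagged upstream).  Codons with 'N' or other ambiguity become 'X'.
    With start_to_met, the first codon is rendered 'M' if it is a
    configured-style alternative start (GTG/TTG); ATG already encodes M.
    """
    nt_seq = nt_seq.upper()
    if len(nt_seq) % 3 != 0:
        raise ValueError(f"sequence length {len(nt_seq)} not divisible by 3")
    if table not in _TABLE_CACHE:
        _TABLE_CACHE[table] = _codon_table(table)
    lookup = _TABLE_CACHE[table]
    codons = [nt_seq[i : i + 3] for i in range(0, len(nt_seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    aas = [lookup.get(c, "X") for c in codons]
    if start_to_met and aas and codons and codons[0] in EXTENDED_START_CODONS:
        aas[0] = "M"
    return "".join(aas)


def cds_length_bp(protein_len: int) -> int:
    """Nucleotide length of a complete CDS encoding `protein_len` residues.

    Includes the stop codon: a 509-residue protein corresponds to a
    1530-bp gene, the 530-residue RebH to 1593 bp.
    """
    if protein_len < 1:
        raise ValueError("protein length must be >= 1")
    return 3 * (protein_len + 1)


@dataclass
class Orf:
    """A predicted gene on a contig.

    start/end are 0-based half-open forward-strand offsets; nt_seq is in
    reading orientation and includes the stop codon iff has_stop.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    frame: int
    nt_seq: str
    protein: ProteinRecord
    has_start: bool
    has_stop: bool

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF span not a codon multiple")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def aa_length(self) -> int:
        return len(self.protein.residues)


def _scan_frame(seq: str, offset: int, min_aa: int, start_codons: frozenset[str],
                table: int) -> list[tuple[int, int, bool, bool]]:
    """Scan one forward frame; return (start, end, has_start, has_stop) in
    frame-local forward coordinates (0-based half-open, stop included when
    present)."""
    n = len(seq)
    results = []
    seg_start = offset          # start of current stop-bounded segment
    at_left_edge = True         # no in-frame stop seen upstream yet
    i = offset
    first_atg = None
    while i + 3 <= n:
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            # close the current segment at this stop
            if at_left_edge:
                begin, has_start = seg_start, False
                # an edge-truncated span: earliest possible start is the edge
            elif first_atg is not None:
                begin, has_start = first_atg, True
            else:
                begin = None
            if at_left_edge or first_atg is not None:
                end = i + 3
                n_codons = (end - begin) // 3 - 1  # minus stop
                if n_codons >= min_aa:
                    results.append((begin, end, has_start, True))
            seg_start = i + 3
            at_left_edge = False
            first_atg = None
        elif first_atg is None and codon in start_codons:
            first_atg = i
        i += 3
    # trailing segment runs off the right edge: no stop codon
    end = i  # last full codon boundary in this frame
    begin = None
    if at_left_edge:
        begin, has_start = seg_start, False
    elif first_atg is not None:
        begin, has_start = first_atg, True
    if begin is not None and end > begin:
        n_codons = (end - begin) // 3
        if n_codons >= min_aa:
            results.append((begin, end, has_start, False))
    return results


def find_orfs(
    contig: Contig,
    min_aa: int = 100,
    start_codons: Iterable[str] = DEFAULT_START_CODONS,
    table: int = 11,
) -> list[Orf]:
    """Predict ORFs in all six frames of a contig.

    Within one stop-bounded segment only the longest (earliest-start) ORF is
    reported.  Segments touching a contig edge are reported as partial
    genes: a segment with no upstream in-frame stop starts at the edge with
    has_start=False; a trailing segment with no stop ends at the edge with
    has_stop=False.  Spans anchored by neither a start nor a stop codon
    (running off both edges) are not reported.  Results are sorted by
    (start, end, strand).
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    start_codons = frozenset(s.upper() for s in start_codons)
    fwd = contig.seq
    rev = reverse_complement(fwd)
    L = len(fwd)
    orfs: list[Orf] = []
    for strand, seq in (("+", fwd), ("-", rev)):
        for frame in range(3):
            for begin, end, has_start, has_stop in _scan_frame(
                seq, frame, min_aa, start_codons, table
            ):
                if not (has_start or has_stop):
                    continue
                nt = seq[begin:end]
                prot = translate(nt, table=table, start_to_met=has_start)
                if strand == "+":
                    f_start, f_end = begin, end
                else:
                    f_start, f_end = L - end, L - begin
                orfs.append(
                    Orf(
                        contig_id=contig.id,
                        start=f_start,
                        end=f_end,
                        strand=strand,
                        frame=frame,
                        nt_seq=nt,
                        protein=ProteinRecord(
                            f"{contig.id}|{f_start}-{f_end}({strand})", prot
                        ),
                        has_start=has_start,
                        has_stop=has_stop,
                    )
                )
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs
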