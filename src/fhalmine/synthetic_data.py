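"""Synthetic metagenome benchmarks with planted halogenase-like genes.

The generator emulates the statistical structure the mining analysis
assumes: assembled contigs of random background DNA carrying (i) complete
variant A- and variant B-like genes reverse-translated from two synthetic
profile HMMs, (ii) edge-truncated partial genes, and (iii) decoys —
shuffled halogenase samples and "monooxygenase-like" sequences retaining
the GxGxxG FAD-binding fingerprint but lacking WxWxIP — together with a
truth manifest for recovery scoring.

The two reference families share a common ancestral consensus; the
variant B model lacks a 70-column block between the catalytic-lysine
region and the WxWxIP motif, reproducing the ~70-aa length offset (and a
different motif spacing) between the variants.  Planted *complete* genes
are rejection-sampled until they genuinely satisfy the completeness
definition (leading Met, both motifs present, length within the filter
window) so the manifest's labels are true by construction.  An in-frame
stop codon is placed immediately upstream of every interior gene so the
ORF finder's earliest-start rule recovers exactly the planted span.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from .annotate import DEFAULT_MOTIFS, FAD_BINDING_MOTIF, WXWXIP_MOTIF, scan_motifs
from .orf_finder import reverse_complement
from .profile_hmm import AA, BACKGROUND, ProfileHmm, build_hmm, sample_sequence
from .seq_io import Contig, Msa, ProteinRecord

DEFAULT_SEED = 1699

_LEN_A = 530
_DELETION_BLOCK = (119, 189)  # 0-based column slice removed in variant B
_MOTIF_GXGXXG = 15            # 0-based start -> residues 16-21
_CATALYTIC_K = 82             # 0-based -> K83
_MOTIF_WXWXIP = 274           # 0-based start -> residues 275-280

_STOPS = ("TAA", "TAG", "TGA")


def _codons_by_aa(table: int = 11) -> dict[str, list[str]]:
    tbl = CodonTable.unambiguous_dna_by_id[table]
    out: dict[str, list[str]] = {}
    for codon, aa in sorted(tbl.forward_table.items()):
        out.setdefault(aa, []).append(codon)
    return out


_CODONS = _codons_by_aa()


@dataclass
class ReferenceModels:
    hmm_a: ProfileHmm
    hmm_b: ProfileHmm
    msa_a: Msa
    msa_b: Msa

    @property
    def ref_ids_a(self) -> list[str]:
        return self.msa_a.ids

    @property
    def ref_ids_b(self) -> list[str]:
        return self.msa_b.ids


def make_reference_models(
    seed: int = DEFAULT_SEED,
    n_seeds: int = 8,
    mutation_rate: float = 0.15,
    class_divergence: float = 0.25,
) -> ReferenceModels:
    """Two synthetic halogenase families and their profile HMMs.

    Variant A: 530 match states with GxGxxG at columns 16-21, K at 83 and
    WxWxIP at 275-280.  Variant B: a diverged subfamily consensus
    (class_divergence of the unconstrained positions substituted) minus a
    70-column block, hence 460 match states with WxWxIP shifted to
    205-210.  Family seeds substitute a further mutation_rate of the
    unconstrained positions, so within-family divergence is smaller than
    the between-family divergence, as in real variant A/B halogenases.
    """
    rng = np.random.default_rng(seed)
    consensus_a = [AA[i] for i in rng.choice(20, size=_LEN_A, p=BACKGROUND)]
    consensus_a[0] = "M"
    fixed = {0: "M", _CATALYTIC_K: "K"}
    for off in (0, 2, 5):
        fixed[_MOTIF_GXGXXG + off] = "G"
    for off, res in ((0, "W"), (2, "W"), (4, "I"), (5, "P")):
        fixed[_MOTIF_WXWXIP + off] = res
    for pos, res in fixed.items():
        consensus_a[pos] = res
    consensus_b = [
        AA[rng.choice(20, p=BACKGROUND)]
        if c not in fixed and rng.random() < class_divergence
        else consensus_a[c]
        for c in range(_LEN_A)
    ]

    def family(prefix: str, consensus: list[str], cols: list[int]) -> Msa:
        rows = []
        for s in range(n_seeds):
            seq = []
            for c in cols:
                if c in fixed:
                    seq.append(fixed[c])
                elif rng.random() < mutation_rate:
                    seq.append(AA[rng.choice(20, p=BACKGROUND)])
                else:
                    seq.append(consensus[c])
            rows.append((f"{prefix}{s + 1}", "".join(seq)))
        return Msa(rows)

    cols_a = list(range(_LEN_A))
    cols_b = [c for c in cols_a if not (_DELETION_BLOCK[0] <= c < _DELETION_BLOCK[1])]
    msa_a = family("refA", consensus_a, cols_a)
    msa_b = family("refB", consensus_b, cols_b)
    # light pseudocounts: the seed alignments are high-confidence, so the
    # generative models keep the motif columns near-deterministic and the
    # indel rates realistically low
    w = 0.05
    return ReferenceModels(
        build_hmm(msa_a, pseudocount_weight=w),
        build_hmm(msa_b, pseudocount_weight=w),
        msa_a,
        msa_b,
    )


def brvh_standin(seed: int = DEFAULT_SEED) -> ProteinRecord:
    """A SYNTHETIC BrvH-like halogenase stand-in (not the NCBI protein).

    Deterministically constructs a 509-residue protein carrying the
    features documented for the Brevundimonas halogenase BrvH: leading
    Met, first GxGxxG match at residues 16-21, catalytic Lys at 83, first
    WxWxIP match at 275-280, and a CDS length of 1530 bp including the
    stop codon.  All unconstrained positions are drawn from the
    background excluding G and W, so the motif matches are unique by
    construction.
    """
    rng = np.random.default_rng(seed)
    no_gw = [i for i, a in enumerate(AA) if a not in "GW"]
    p = BACKGROUND[no_gw] / BACKGROUND[no_gw].sum()
    seq = [AA[no_gw[i]] for i in rng.choice(len(no_gw), size=509, p=p)]
    seq[0] = "M"
    for off in (0, 2, 5):
        seq[_MOTIF_GXGXXG + off] = "G"
    seq[_CATALYTIC_K] = "K"
    for off, res in ((0, "W"), (2, "W"), (4, "I"), (5, "P")):
        seq[_MOTIF_WXWXIP + off] = res
    return ProteinRecord("BrvH-synthetic-standin", "".join(seq))


# ---------------------------------------------------------------------------
# Benchmark configuration and manifest


@dataclass
class BenchmarkConfig:
    """Defaults echo the cohort shape reported for the Botany Bay sample
    (42 complete genes among 254 planted elements) purely as a familiar
    default; this is a synthetic benchmark, not a reproduction of any
    real metagenome's counts."""

    n_contigs: int = 60
    contig_length: tuple[int, int] = (8000, 20000)
    n_complete_a: int = 30
    n_complete_b: int = 12
    n_partial: int = 112
    n_decoys: int = 100
    truncation_fraction: float = 0.4
    gc: float = 0.5
    len_min: int = 460
    len_max: int = 600
    min_spacer: int = 50
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        for name in ("n_contigs", "n_complete_a", "n_complete_b", "n_partial",
                     "n_decoys"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.truncation_fraction < 1:
            raise ValueError("truncation_fraction must lie in (0, 1)")
        if not 0 < self.gc < 1:
            raise ValueError("gc must lie in (0, 1)")
        lo, hi = self.contig_length
        if lo < 1 or hi < lo:
            raise ValueError("invalid contig_length range")
        total = self.n_complete_a + self.n_complete_b + self.n_partial + self.n_decoys
        if total > 0 and lo < 3 * 3 * (self.len_min + 1):
            raise ValueError(
                "minimum contig length must be at least 3x the minimum gene "
                "length when genes are planted"
            )

    @property
    def n_planted(self) -> int:
        return self.n_complete_a + self.n_complete_b + self.n_partial + self.n_decoys


@dataclass
class PlantedGene:
    contig_id: str
    start: int            # 0-based half-open forward-strand span
    end: int
    strand: str
    klass: str            # "A", "B", or "decoy"
    completeness: str     # "complete" or "partial"
    source_model: str
    protein_length: int


@dataclass
class TruthManifest:
    entries: list[PlantedGene]
    seed: int
    model_seed: int = DEFAULT_SEED  # rebuilds the reference models used

    def count(self, klass: str | None = None, completeness: str | None = None) -> int:
        return sum(
            1
            for e in self.entries
            if (klass is None or e.klass == klass)
            and (completeness is None or e.completeness == completeness)
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "model_seed": self.model_seed,
                    "entries": [asdict(e) for e in self.entries],
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            [PlantedGene(**e) for e in obj["entries"]],
            obj["seed"],
            obj.get("model_seed", DEFAULT_SEED),
        )


# ---------------------------------------------------------------------------
# Element construction


def _reverse_translate(protein: str, rng: np.random.Generator,
                       add_stop: bool = True) -> str:
    codons = []
    for aa in protein:
        opts = _CODONS[aa]
        codons.append(opts[int(rng.integers(len(opts)))])
    if add_stop:
        codons.append(_STOPS[int(rng.integers(3))])
    return "".join(codons)


def _has_motifs(residues: str) -> tuple[bool, bool]:
    rec = ProteinRecord("x", residues)
    hits = scan_motifs(rec, DEFAULT_MOTIFS)
    names = {h.motif for h in hits}
    return FAD_BINDING_MOTIF.name in names, WXWXIP_MOTIF.name in names


def _sample_complete(hmm: ProfileHmm, cfg: BenchmarkConfig,
                     rng: np.random.Generator, max_tries: int = 200) -> str:
    """Rejection-sample a protein satisfying the completeness definition."""
    for _ in range(max_tries):
        p = sample_sequence(hmm, int(rng.integers(2**31))).residues
        if not p.startswith("M"):
            continue
        if not (cfg.len_min <= len(p) <= cfg.len_max):
            continue
        g, w = _has_motifs(p)
        if g and w:
            return p
    raise RuntimeError("could not sample a complete gene; model too noisy")


def _sample_shuffled_decoy(hmm: ProfileHmm, rng: np.random.Generator) -> str:
    for _ in range(100):
        p = list(sample_sequence(hmm, int(rng.integers(2**31))).residues)
        body = p[1:]
        rng.shuffle(body)
        seq = "M" + "".join(body)
        _, w = _has_motifs(seq)
        if not w:
            return seq
    raise RuntimeError("shuffling kept producing WxWxIP matches")


def _sample_monooxygenase_decoy(hmm: ProfileHmm, rng: np.random.Generator) -> str:
    """A halogenase-like sequence with GxGxxG retained and WxWxIP ablated:
    scores well under the model but fails the motif filter."""
    for _ in range(200):
        p = list(sample_sequence(hmm, int(rng.integers(2**31))).residues)
        p[0] = "M"
        seq = "".join(p)
        for _ in range(20):
            hits = [h for h in scan_motifs(ProteinRecord("x", seq), [WXWXIP_MOTIF])]
            if not hits:
                break
            i = hits[0].start - 1
            seq = seq[:i] + "D" + seq[i + 1 :]  # kill the first W
        g, w = _has_motifs(seq)
        if g and not w:
            return seq
    raise RuntimeError("could not construct a monooxygenase-like decoy")


# ---------------------------------------------------------------------------
# Benchmark assembly


def _background(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=p))


def make_benchmark(cfg: BenchmarkConfig | None = None):
    """Generate contigs and a truth manifest.

    Interior genes (complete and decoy) are planted on a random strand
    behind an in-frame guard stop; partial genes sit flush against a
    contig edge on the forward strand with truncation_fraction of their
    codons removed (head-truncation kills the start, tail-truncation the
    stop).  Returns (contigs, manifest).
    """
    cfg = cfg or BenchmarkConfig()
    if cfg.n_partial > 2 * cfg.n_contigs:
        raise ValueError(
            f"{cfg.n_partial} partial genes do not fit on "
            f"{cfg.n_contigs} contigs (2 edges each)"
        )
    rng = np.random.default_rng(cfg.seed)
    model_seed = int(rng.integers(2**31))
    models = make_reference_models(model_seed)

    elements = []  # (kind, klass, source, protein)
    for _ in range(cfg.n_complete_a):
        elements.append(
            ("complete", "A", "hmmA", _sample_complete(models.hmm_a, cfg, rng))
        )
    for _ in range(cfg.n_complete_b):
        elements.append(
            ("complete", "B", "hmmB", _sample_complete(models.hmm_b, cfg, rng))
        )
    for i in range(cfg.n_partial):
        klass = "A" if i % 2 == 0 else "B"
        hmm = models.hmm_a if klass == "A" else models.hmm_b
        elements.append(("partial", klass, f"hmm{klass}", _sample_complete(hmm, cfg, rng)))
    for i in range(cfg.n_decoys):
        if i % 2 == 0:
            elements.append(
                ("decoy", "decoy", "shuffle",
                 _sample_shuffled_decoy(models.hmm_a, rng))
            )
        else:
            elements.append(
                ("decoy", "decoy", "monooxygenase-like",
                 _sample_monooxygenase_decoy(models.hmm_a, rng))
            )

    interior = [e for e in elements if e[0] != "partial"]
    partials = [e for e in elements if e[0] == "partial"]
    order = rng.permutation(len(interior))
    interior = [interior[i] for i in order]

    n = cfg.n_contigs
    per_contig_interior: list[list] = [[] for _ in range(n)]
    for i, el in enumerate(interior):
        per_contig_interior[i % n].append(el)
    left_partial: list = [None] * n
    right_partial: list = [None] * n
    for i, el in enumerate(partials):
        c = i % n
        if left_partial[c] is None:
            left_partial[c] = el
        else:
            right_partial[c] = el

    contigs: list[Contig] = []
    entries: list[PlantedGene] = []
    lo, hi = cfg.contig_length
    for c in range(n):
        cid = f"contig{c + 1:03d}"
        target = int(rng.integers(lo, hi + 1))
        parts: list[str] = []
        pos = 0

        def put(s: str) -> None:
            nonlocal pos
            parts.append(s)
            pos += len(s)

        if left_partial[c] is not None:
            _, klass, source, prot = left_partial[c]
            nt = _reverse_translate(prot, rng)
            cut = 3 * int(round(cfg.truncation_fraction * len(prot)))
            rem = nt[cut:]
            entries.append(
                PlantedGene(cid, 0, len(rem), "+", klass, "partial", source,
                            len(prot) - cut // 3)
            )
            put(rem)
        for kind, klass, source, prot in per_contig_interior[c]:
            put(_background(int(rng.integers(cfg.min_spacer, 301)), cfg.gc, rng))
            nt = _reverse_translate(prot, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                put("TAA")  # in-frame guard upstream of the start codon
                entries.append(
                    PlantedGene(cid, pos, pos + len(nt), strand, klass,
                                "complete", source, len(prot))
                )
                put(nt)
            else:
                entries.append(
                    PlantedGene(cid, pos, pos + len(nt), strand, klass,
                                "complete", source, len(prot))
                )
                put(reverse_complement(nt))
                put("TTA")  # guard, reverse-strand reading frame
        tail = right_partial[c]
        tail_nt = ""
        if tail is not None:
            _, klass, source, prot = tail
            nt = _reverse_translate(prot, rng)
            keep = len(prot) - int(round(cfg.truncation_fraction * len(prot)))
            tail_nt = nt[: 3 * keep]
        pad = target - pos - (len(tail_nt) + 303 if tail is not None else 0)
        if pad > 0:
            put(_background(pad, cfg.gc, rng))
        if tail is not None:
            put(_background(int(rng.integers(cfg.min_spacer, 301)), cfg.gc, rng))
            put("TAA")
            entries.append(
                PlantedGene(cid, pos, pos + len(tail_nt), "+", klass, "partial",
                            source, keep)
            )
            put(tail_nt)
        contigs.append(Contig(cid, "".join(parts), source="synthetic-benchmark"))
    return contigs, TruthManifest(entries, cfg.seed, model_seed)


# ---------------------------------------------------------------------------
# Recovery scoring


def score_recovery(candidates, manifest: TruthManifest, min_overlap: float = 0.8,
                   contig_ids: set[str] | None = None):
    """Compare pipeline candidates with the planted truth.

    `candidates` is an iterable of objects (or the pipeline's candidate
    records) with attributes contig_id, start, end, strand, passed_evalue
    and complete (bool) and variant (call string or None).  A planted gene
    counts as recovered iff a candidate overlaps >= min_overlap of its
    span on the correct strand — for the complete stratum the candidate
    must additionally carry a complete verdict.  Returns a dict with
    per-stratum recall, per-class precision, pooled complete-gene recall
    and the decoy false-positive count (complete-verdict candidates
    matching a decoy or nothing).
    """
    by_contig: dict[str, list[PlantedGene]] = {}
    for e in manifest.entries:
        by_contig.setdefault(e.contig_id, []).append(e)

    detected: dict[int, bool] = {}
    complete_hit: dict[int, bool] = {}
    cand_match: list[tuple[object, PlantedGene | None]] = []
    for cand in candidates:
        if not getattr(cand, "passed_evalue", True):
            continue
        if contig_ids is not None and cand.contig_id not in contig_ids:
            raise ValueError(
                f"candidate contig {cand.contig_id!r} not in the benchmark"
            )
        best = None
        best_ov = 0.0
        for e in by_contig.get(cand.contig_id, []):
            if e.strand != cand.strand:
                continue
            ov = min(cand.end, e.end) - max(cand.start, e.start)
            frac = ov / (e.end - e.start)
            if frac >= min_overlap and frac > best_ov:
                best, best_ov = e, frac
        cand_match.append((cand, best))
        if best is not None:
            i = id(best)
            detected[i] = True
            if getattr(cand, "complete", False):
                complete_hit[i] = True

    recall: dict[tuple[str, str], float | None] = {}
    pooled_num = pooled_den = 0
    for klass in ("A", "B"):
        for stratum in ("complete", "partial"):
            planted = [
                e for e in manifest.entries
                if e.klass == klass and e.completeness == stratum
            ]
            if not planted:
                recall[(klass, stratum)] = None
                continue
            if stratum == "complete":
                got = sum(1 for e in planted if complete_hit.get(id(e), False))
                pooled_num += got
                pooled_den += len(planted)
            else:
                got = sum(1 for e in planted if detected.get(id(e), False))
            recall[(klass, stratum)] = got / len(planted)

    precision: dict[str, float | None] = {}
    for klass in ("A", "B"):
        claimed = [
            (c, m) for c, m in cand_match
            if getattr(c, "complete", False) and getattr(c, "variant", None) == klass
        ]
        if not claimed:
            precision[klass] = None
        else:
            tp = sum(
                1 for _, m in claimed
                if m is not None and m.klass == klass and m.completeness == "complete"
            )
            precision[klass] = tp / len(claimed)

    decoy_fp = sum(
        1 for c, m in cand_match
        if getattr(c, "complete", False) and (m is None or m.klass == "decoy")
    )
    return {
        "recall": recall,
        "precision": precision,
        "complete_recall": (pooled_num / pooled_den) if pooled_den else None,
        "decoy_false_positives": decoy_fp,
        "n_candidates_matched": sum(1 for _, m in cand_match if m is not None),
    }
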