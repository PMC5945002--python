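"""End-to-end halogenase mining: ORF prediction -> HMM scan -> E-value
filter -> completeness filter -> phylogenetic variant classification,
with per-stage attrition accounting and deterministic artifacts.

The candidate unit is the ORF: overlapping predictions are resolved by
best bit score.  The literature E-value cutoff of 1e-150 was defined
against HMMER3's E-values and is carried only as provenance metadata
(`paper_evalue_cutoff`); the operational cutoff for this package's scorer
defaults to 1e-6 against its own Gumbel calibration.
"""

from __future__ import annotations

import json
import logging
import tomllib
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .alignment import HomologSearchConfig, collect_homologs, progressive_msa
from .annotate import (
    CompletenessConfig,
    CompletenessReport,
    MotifHit,
    ResidueMapping,
    assess_completeness,
    first_hit,
    map_catalytic_residues,
    scan_motifs,
)
from .orf_finder import Orf, find_orfs
from .phylo import (
    DEFAULT_BOOTSTRAP_REPS,
    PhyloTree,
    VariantCall,
    VariantLengthPrior,
    bootstrap_support,
    classify_variant,
)
from .profile_hmm import (
    DEFAULT_SEED,
    HmmHit,
    ProfileHmm,
    build_hmm,
    calibrate,
    codon_background,
    hit as score_hit,
)
from .seq_io import (
    Contig,
    ProteinRecord,
    read_fasta,
    read_msa_fasta,
    write_gff3,
    write_msa_fasta,
    write_newick,
)

logger = logging.getLogger(__name__)

PAPER_EVALUE_CUTOFF = 1e-150  # HMMER3 scale; provenance only, never applied


@dataclass
class PipelineConfig:
    contigs: str | None = None
    hmm: str | None = None
    seed_msa: str | None = None
    refs_a: str | None = None
    refs_b: str | None = None
    outdir: str | None = None
    min_aa: int = 100
    start_codons: tuple[str, ...] = ("ATG",)
    table: int = 11
    evalue_max: float = 1e-6
    paper_evalue_cutoff: float = PAPER_EVALUE_CUTOFF
    completeness: CompletenessConfig = field(default_factory=CompletenessConfig)
    calib_decoys: int = 200
    calib_length: int = 150
    calib_null: str = "codon"  # "codon": random-DNA ORF null; "model": background
    bootstrap_reps: int = DEFAULT_BOOTSTRAP_REPS
    distance_correction: str = "none"
    seed: int = DEFAULT_SEED

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        comp = raw.pop("completeness", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "completeness"})
        if comp:
            cfg.completeness = CompletenessConfig(**comp)
        if isinstance(cfg.start_codons, list):
            cfg.start_codons = tuple(cfg.start_codons)
        return cfg


@dataclass
class Candidate:
    """One scored ORF with its annotations and verdicts."""

    orf: Orf
    hit: HmmHit
    passed_evalue: bool
    motif_hits: list[MotifHit] = field(default_factory=list)
    catalytic: list[ResidueMapping] = field(default_factory=list)
    completeness: CompletenessReport | None = None
    variant_call: VariantCall | None = None

    # flat accessors (duck-typed by the recovery scorer)
    @property
    def contig_id(self) -> str:
        return self.orf.contig_id

    @property
    def start(self) -> int:
        return self.orf.start

    @property
    def end(self) -> int:
        return self.orf.end

    @property
    def strand(self) -> str:
        return self.orf.strand

    @property
    def complete(self) -> bool:
        return self.completeness is not None and self.completeness.complete

    @property
    def variant(self) -> str | None:
        return None if self.variant_call is None else self.variant_call.call


@dataclass
class CandidateReport:
    candidates: list[Candidate]
    attrition: dict[str, int]
    tree: PhyloTree | None
    summary: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            g = first_hit(c.motif_hits, "GxGxxG")
            w = first_hit(c.motif_hits, "WxWxIP")
            comp = c.completeness
            rows.append(
                {
                    "id": c.orf.protein.id,
                    "contig": c.contig_id,
                    "start": c.start + 1,  # 1-based inclusive on disk
                    "end": c.end,
                    "strand": c.strand,
                    "frame": c.orf.frame,
                    "has_start": c.orf.has_start,
                    "has_stop": c.orf.has_stop,
                    "aa_length": c.orf.aa_length,
                    "bit_score": round(c.hit.bit_score, 3),
                    "evalue": f"{c.hit.evalue:.3g}",
                    "passed_evalue": c.passed_evalue,
                    "gxgxxg_start": g.start if g else None,
                    "wxwxip_start": w.start if w else None,
                    "catalytic_ok": all(m.match for m in c.catalytic)
                    if c.catalytic
                    else None,
                    "complete": c.complete,
                    "reasons": "; ".join(comp.reasons) if comp else "",
                    "variant": c.variant,
                    "variant_evidence": c.variant_call.evidence
                    if c.variant_call
                    else None,
                }
            )
        return pd.DataFrame(rows)


def _overlap_filter(cands: list[Candidate]) -> list[Candidate]:
    """Best bit score wins among overlapping predictions (any frame or
    strand, >50% of the shorter span shared)."""
    kept: list[Candidate] = []
    for c in sorted(cands, key=lambda x: (-x.hit.bit_score, x.contig_id, x.start)):
        clash = False
        for k in kept:
            if k.contig_id != c.contig_id:
                continue
            ov = min(k.end, c.end) - max(k.start, c.start)
            if ov > 0.5 * min(k.end - k.start, c.end - c.start):
                clash = True
                break
        if not clash:
            kept.append(c)
    kept.sort(key=lambda x: (x.contig_id, x.start))
    return kept


def run_mining(
    cfg: PipelineConfig,
    contigs: list[Contig] | None = None,
    hmm: ProfileHmm | None = None,
    refs_a: list[ProteinRecord] | None = None,
    refs_b: list[ProteinRecord] | None = None,
    anchors: list[tuple[str, int, str]] | None = None,
) -> CandidateReport:
    """Run the full mining pipeline; deterministic given cfg.seed.

    Inputs may be passed in memory or read from the paths in cfg.  Writes
    GFF3/TSV/Newick/JSON artifacts when cfg.outdir is set.
    """
    if contigs is None:
        if cfg.contigs is None:
            raise ValueError("no contigs given (cfg.contigs unset)")
        contigs = read_fasta(cfg.contigs, "dna")
    if hmm is None:
        if cfg.hmm:
            hmm = ProfileHmm.from_json(cfg.hmm)
        elif cfg.seed_msa:
            hmm = build_hmm(read_msa_fasta(cfg.seed_msa))
        else:
            raise ValueError("no model given (cfg.hmm / cfg.seed_msa unset)")
    if hmm.calibration is None:
        comp = codon_background() if cfg.calib_null == "codon" else None
        hmm.calibration = calibrate(
            hmm, n_decoys=cfg.calib_decoys, decoy_length=cfg.calib_length,
            seed=cfg.seed, composition=comp,
        )
    if refs_a is None and cfg.refs_a:
        refs_a = read_fasta(cfg.refs_a, "protein")
    if refs_b is None and cfg.refs_b:
        refs_b = read_fasta(cfg.refs_b, "protein")

    # stage 1: gene prediction
    orfs: list[Orf] = []
    for contig in contigs:
        orfs.extend(find_orfs(contig, cfg.min_aa, cfg.start_codons, cfg.table))
    attrition = {"predicted": len(orfs)}
    if not orfs:
        warnings.warn("no ORFs predicted; returning an empty report")
        attrition.update(scored=0, evalue_pass=0, complete=0, classified=0)
        report = CandidateReport([], attrition, None, _summary(cfg, hmm, attrition))
        _write_artifacts(report, cfg)
        return report

    # stage 2: HMM scoring (database size = number of scored genes)
    db_size = len(orfs)
    cands = [
        Candidate(orf=o, hit=score_hit(hmm, o.protein, db_size=db_size),
                  passed_evalue=False)
        for o in orfs
    ]
    attrition["scored"] = len(cands)
    cands = _overlap_filter(cands)

    # stage 3: E-value filter
    for c in cands:
        c.passed_evalue = c.hit.evalue <= cfg.evalue_max
    passed = [c for c in cands if c.passed_evalue]
    attrition["evalue_pass"] = len(passed)

    # stage 4: motifs + completeness
    for c in passed:
        c.motif_hits = scan_motifs(c.orf.protein)
        if anchors:
            c.catalytic = map_catalytic_residues(c.orf.protein, hmm, anchors)
        c.completeness = assess_completeness(
            c.orf, c.motif_hits, c.hit, cfg.completeness
        )
    complete = [c for c in passed if c.complete]
    attrition["complete"] = len(complete)

    # stage 5: phylogenetic classification of complete candidates
    tree = None
    n_classified = 0
    if complete and refs_a and refs_b and len(refs_a) >= 2 and len(refs_b) >= 2:
        taxa = refs_a + refs_b + [c.orf.protein for c in complete]
        msa = progressive_msa(taxa)
        tree = bootstrap_support(
            msa, n_reps=cfg.bootstrap_reps, seed=cfg.seed,
            correction=cfg.distance_correction,
        )
        ids_a = {r.id for r in refs_a}
        ids_b = {r.id for r in refs_b}
        prior = VariantLengthPrior(
            mean_len_a=sum(len(r) for r in refs_a) / len(refs_a)
        )
        for c in complete:
            c.variant_call = classify_variant(
                tree, ids_a, ids_b, c.orf.protein.id,
                query_length=c.orf.aa_length, length_prior=prior,
            )
            n_classified += 1
    attrition["classified"] = n_classified

    order = ["predicted", "scored", "evalue_pass", "complete", "classified"]
    for a, b in zip(order, order[1:]):
        if attrition[b] > attrition[a]:
            raise AssertionError(f"attrition increased from {a} to {b}")

    report = CandidateReport(cands, attrition, tree, _summary(cfg, hmm, attrition))
    _write_artifacts(report, cfg)
    return report


def _summary(cfg: PipelineConfig, hmm: ProfileHmm, attrition: dict) -> dict:
    cal = hmm.calibration
    return {
        "tool": "fhalmine",
        "version": __version__,
        "seed": cfg.seed,
        "evalue_max": cfg.evalue_max,
        "paper_evalue_cutoff": cfg.paper_evalue_cutoff,
        "paper_evalue_note": (
            "the 1e-150 cutoff is defined against HMMER3 E-values and is "
            "not applied by this scorer; see evalue_max"
        ),
        "min_aa": cfg.min_aa,
        "start_codons": list(cfg.start_codons),
        "completeness": asdict(cfg.completeness),
        "bootstrap_reps": cfg.bootstrap_reps,
        "model_length": hmm.L,
        "calibration": None
        if cal is None
        else {"mu": cal.mu, "lam": cal.lam, "n_decoys": cal.n_decoys,
              "seed": cal.seed},
        "attrition": dict(attrition),
    }


def _write_artifacts(report: CandidateReport, cfg: PipelineConfig) -> None:
    if not cfg.outdir:
        return
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_gff3([c.orf for c in report.candidates], out / "orfs.gff3")
    report.to_frame().to_csv(out / "candidates.tsv", sep="\t", index=False)
    if report.tree is not None:
        write_newick(report.tree, out / "tree.nwk")
    with open(out / "summary.json", "w") as fh:
        json.dump(report.summary, fh, indent=1, sort_keys=True)


def run_hmm_construction(
    refs: list[ProteinRecord],
    database: list[ProteinRecord],
    cfg: HomologSearchConfig | None = None,
    calib_decoys: int = 200,
    calib_length: int = 150,
    seed: int = DEFAULT_SEED,
    msa_out: str | Path | None = None,
) -> ProfileHmm:
    """Two-step model construction: collect homologs of the characterized
    references at the identity/coverage thresholds, align them
    progressively, build the profile HMM, calibrate its E-values."""
    if not refs:
        raise ValueError("no reference sequences")
    kept = collect_homologs(refs, database, cfg)
    by_id = {r.id: r for r in refs}
    for r in kept:
        by_id.setdefault(r.id, r)
    training = list(by_id.values())
    if len(training) < 2:
        raise ValueError("fewer than 2 sequences retained; cannot build a model")
    msa = progressive_msa(training, cfg)
    if msa_out:
        write_msa_fasta(msa, msa_out)
    hmm = build_hmm(msa)
    hmm.calibration = calibrate(
        hmm, n_decoys=calib_decoys, decoy_length=calib_length, seed=seed,
        composition=codon_background(),
    )
    return hmm
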