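"""Conserved-motif scanning, catalytic-residue mapping, and the
completeness filter.

Flavin-dependent halogenases carry a Rossmann-like FAD-binding fingerprint
(GxGxxG) near the N terminus, a WxWxIP motif thought to block
monooxygenase activity, and a conserved catalytic lysine/glutamate pair
(K79/E346 in PrnA numbering).  A candidate gene is *complete* when it has
a start and a stop codon, the required conserved regions are present, its
length fits known halogenases, and its model E-value passes the cutoff.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .orf_finder import Orf
from .profile_hmm import HmmHit, ProfileHmm, viterbi
from .seq_io import ProteinRecord


@dataclass
class MotifDefinition:
    """Degenerate residue pattern: 'x' matches anything, a letter itself."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if len(self.pattern) < 2:
            raise ValueError("motif pattern must have length >= 2")
        if not re.fullmatch(r"[A-Zx]+", self.pattern):
            raise ValueError(
                f"motif {self.name}: only uppercase letters and 'x' allowed"
            )

    @property
    def regex(self) -> re.Pattern:
        body = "".join("." if c == "x" else c for c in self.pattern)
        return re.compile(f"(?=({body}))")


FAD_BINDING_MOTIF = MotifDefinition("GxGxxG", "GxGxxG")
WXWXIP_MOTIF = MotifDefinition("WxWxIP", "WxWxIP")
DEFAULT_MOTIFS = [FAD_BINDING_MOTIF, WXWXIP_MOTIF]


@dataclass
class MotifHit:
    motif: str
    start: int  # 1-based inclusive
    end: int
    matched: str


def scan_motifs(
    protein: ProteinRecord, motifs: list[MotifDefinition] | None = None
) -> list[MotifHit]:
    """All (possibly overlapping) motif matches, ascending by start."""
    motifs = DEFAULT_MOTIFS if motifs is None else motifs
    hits: list[MotifHit] = []
    for m in motifs:
        for match in m.regex.finditer(protein.residues):
            s = match.start() + 1
            hits.append(
                MotifHit(m.name, s, s + len(m.pattern) - 1, match.group(1))
            )
    hits.sort(key=lambda h: (h.motif, h.start))
    return hits


def first_hit(hits: list[MotifHit], motif: str) -> MotifHit | None:
    for h in hits:
        if h.motif == motif:
            return h
    return None


# ---------------------------------------------------------------------------
# Catalytic-residue mapping


@dataclass
class ResidueMapping:
    anchor: tuple[str, int, str]      # (reference id, reference position, residue)
    position: int | None              # 1-based position in the query, None if deleted
    observed: str | None
    match: bool


def map_catalytic_residues(
    protein: ProteinRecord,
    hmm: ProfileHmm,
    anchors: list[tuple[str, int, str]],
) -> list[ResidueMapping]:
    """Project reference residue positions onto a query via match columns.

    Each anchor (reference id, 1-based reference position, expected
    residue) is located in the model's match columns through the
    reference's stored residue-to-column map (the reference must be a row
    of the training MSA), then mapped onto the query through its Viterbi
    residue-to-column map.  Columns deleted in the query yield
    position=None, match=False.
    """
    _, _, qmap = viterbi(hmm, protein)
    col_to_qpos = {col: pos for pos, col in qmap}
    out: list[ResidueMapping] = []
    for ref_id, ref_pos, expected in anchors:
        if ref_id not in hmm.training_maps:
            raise ValueError(f"anchor reference {ref_id!r} not in the training MSA")
        ref_map = dict(hmm.training_maps[ref_id])  # residue pos -> column
        ref_len = max(ref_map) if ref_map else 0
        if ref_pos < 1:
            raise ValueError(f"anchor position {ref_pos} out of range")
        if ref_pos not in ref_map:
            # position exists in the reference but sits in an insert column
            # (or beyond its length): it cannot be projected
            if ref_pos > ref_len:
                raise ValueError(
                    f"anchor position {ref_pos} beyond reference {ref_id!r}"
                )
            out.append(ResidueMapping((ref_id, ref_pos, expected), None, None, False))
            continue
        col = ref_map[ref_pos]
        qpos = col_to_qpos.get(col)
        if qpos is None:
            out.append(ResidueMapping((ref_id, ref_pos, expected), None, None, False))
        else:
            obs = protein.residues[qpos - 1]
            out.append(
                ResidueMapping(
                    (ref_id, ref_pos, expected), qpos, obs, obs == expected
                )
            )
    return out


# ---------------------------------------------------------------------------
# Completeness filter


@dataclass
class CompletenessConfig:
    require_start: bool = True
    require_stop: bool = True
    required_motifs: list[str] = field(
        default_factory=lambda: ["GxGxxG", "WxWxIP"]
    )
    len_min: int = 460
    len_max: int = 600
    evalue_max: float = 1e-6

    def __post_init__(self) -> None:
        if self.len_min >= self.len_max:
            raise ValueError("len_min must be < len_max")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")


@dataclass
class CompletenessReport:
    start_stop: bool
    motifs: bool
    length: bool
    evalue: bool
    reasons: list[str]

    @property
    def complete(self) -> bool:
        return self.start_stop and self.motifs and self.length and self.evalue


def assess_completeness(
    orf: Orf,
    hits: list[MotifHit],
    hmm_hit: HmmHit,
    cfg: CompletenessConfig | None = None,
) -> CompletenessReport:
    """Apply the completeness criteria to one candidate gene."""
    cfg = cfg or CompletenessConfig()
    reasons: list[str] = []
    start_stop = (orf.has_start or not cfg.require_start) and (
        orf.has_stop or not cfg.require_stop
    )
    if not start_stop:
        missing = []
        if cfg.require_start and not orf.has_start:
            missing.append("start codon")
        if cfg.require_stop and not orf.has_stop:
            missing.append("stop codon")
        reasons.append("missing " + " and ".join(missing))
    present = {h.motif for h in hits}
    absent = [m for m in cfg.required_motifs if m not in present]
    motifs_ok = not absent
    if not motifs_ok:
        reasons.append("conserved region(s) absent: " + ", ".join(absent))
    n = orf.aa_length
    length_ok = cfg.len_min <= n <= cfg.len_max
    if not length_ok:
        reasons.append(
            f"protein length {n} outside [{cfg.len_min}, {cfg.len_max}] aa"
        )
    evalue_ok = hmm_hit.evalue <= cfg.evalue_max
    if not evalue_ok:
        reasons.append(f"E-value {hmm_hit.evalue:.3g} > {cfg.evalue_max:.3g}")
    return CompletenessReport(start_stop, motifs_ok, length_ok, evalue_ok, reasons)
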