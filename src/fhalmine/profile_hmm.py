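"""Minimal profile hidden Markov model for protein-family search.

A position-specific model with match/insert/delete states is built from a
multiple alignment, scores sequences with the Forward and Viterbi
algorithms under a single-hit *local* alignment architecture (free
background-emitting flanks, uniform entry over match states, a small
constant per-column exit probability), samples sequences generatively, and
calibrates E-values by fitting a Gumbel distribution to the Forward scores
of i.i.d. background decoys.

Scores are reported in bits: log2 P(seq | model) / P(seq | background).
E-values from this scorer are NOT numerically comparable to HMMER3's;
any literature cutoff defined against HMMER E-values must be re-derived
for this scorer (see the calibration utilities).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from . import _dp
from .seq_io import Msa, ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}

# Robinson & Robinson style amino-acid background frequencies (normalized).
_BG_RAW = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.04074,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05130,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}
BACKGROUND = np.array([_BG_RAW[a] for a in AA])
BACKGROUND = BACKGROUND / BACKGROUND.sum()

DEFAULT_SEED = 1699

_LOG0 = _dp.NEG_INF


def _safe_log(x: np.ndarray | float):
    return np.where(np.asarray(x) > 0, np.log(np.maximum(x, 1e-300)), _LOG0)


def encode_protein(residues: str) -> np.ndarray:
    """Map residues to integer codes; 'X' becomes the neutral code 20
    (emission odds 1 in every state).  Other symbols are rejected."""
    out = np.empty(len(residues), dtype=np.int64)
    for i, r in enumerate(residues):
        if r in AA_INDEX:
            out[i] = AA_INDEX[r]
        elif r == "X":
            out[i] = 20
        else:
            raise ValueError(f"residue {r!r} at position {i + 1} not in alphabet")
    return out


@dataclass
class GumbelFit:
    """Location/scale of the null (decoy) Forward-score distribution."""

    mu: float
    lam: float
    n_decoys: int
    seed: int

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("Gumbel scale parameter lam must be > 0")
        if self.n_decoys < 100:
            raise ValueError("need at least 100 decoys for a stable fit")


@dataclass
class HmmHit:
    seq_id: str
    bit_score: float
    evalue: float
    ali_start: int  # 1-based residue span of the Viterbi hit
    ali_end: int


@dataclass
class ProfileHmm:
    """Match/insert/delete emission+transition model over 20 residues.

    Core transition bundles (per match column k, 0-based arrays):
      mm/mi/md : M_k ->  M_{k+1} / I_k / D_{k+1}
      im/ii    : I_k ->  M_{k+1} / I_k
      dm/dd    : D_k ->  M_{k+1} / D_{k+1}
    Local-alignment scoring adds uniform entry 1/L, constant per-column
    exit probability `exit_prob`, and flanking self-loops `flank_loop`.
    """

    L: int
    match_emit: np.ndarray          # (L, 20)
    insert_emit: np.ndarray         # (20,)
    trans: dict[str, np.ndarray]    # each (L,)
    background: np.ndarray          # (20,)
    exit_prob: float = 0.01
    flank_loop: float = 0.98
    calibration: GumbelFit | None = None
    match_columns: list[int] = field(default_factory=list)   # MSA col idx
    training_maps: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("model must have at least one match state")
        self._kernel_args = None
        self.validate()

    def validate(self, tol: float = 1e-9) -> None:
        if self.match_emit.shape != (self.L, 20):
            raise ValueError("match_emit shape mismatch")
        if not np.allclose(self.match_emit.sum(axis=1), 1.0, atol=tol):
            raise ValueError("match emission rows must sum to 1")
        if not math.isclose(self.insert_emit.sum(), 1.0, abs_tol=tol):
            raise ValueError("insert emissions must sum to 1")
        if not math.isclose(self.background.sum(), 1.0, abs_tol=tol):
            raise ValueError("background must sum to 1")
        t = self.trans
        if self.L > 1:
            core = t["mm"][:-1] + t["mi"][:-1] + t["md"][:-1]
            if not np.allclose(core, 1.0, atol=tol):
                raise ValueError("M-state transition bundles must sum to 1")
            if not np.allclose(t["im"][:-1] + t["ii"][:-1], 1.0, atol=tol):
                raise ValueError("I-state transition bundles must sum to 1")
            if not np.allclose(t["dm"][:-1] + t["dd"][:-1], 1.0, atol=tol):
                raise ValueError("D-state transition bundles must sum to 1")
        if not 0 < self.exit_prob <= 1:
            raise ValueError("exit_prob must be in (0, 1]")
        if not 0 <= self.flank_loop < 1:
            raise ValueError("flank_loop must be in [0, 1)")

    # -- scoring ----------------------------------------------------------

    def _kernel(self):
        if self._kernel_args is not None:
            return self._kernel_args
        L = self.L
        lme = np.full((L + 1, 21), _LOG0)
        lme[1:, :20] = _safe_log(self.match_emit)
        lme[:, 20] = 0.0  # 'X': odds ratio 1 by construction
        lie = np.zeros(21)
        lie[:20] = _safe_log(self.insert_emit)
        lbg = np.zeros(21)
        lbg[:20] = _safe_log(self.background)
        mu = self.exit_prob
        keep = math.log1p(-mu) if mu < 1 else _LOG0
        pad = np.full(L + 1, _LOG0)

        def core(name):
            a = pad.copy()
            a[1:] = _safe_log(self.trans[name])
            return a

        ltmm = core("mm") + keep
        ltmi = core("mi") + keep
        ltmd = core("md") + keep
        ltim = core("im")
        ltii = core("ii")
        ltdm = core("dm")
        ltdd = core("dd")
        ltme = np.full(L + 1, math.log(mu))
        ltme[0] = _LOG0
        ltme[L] = 0.0
        ltmm[L] = ltmi[L] = ltmd[L] = _LOG0
        ltde = np.full(L + 1, _LOG0)
        ltde[L] = 0.0
        ltdm[L] = ltdd[L] = _LOG0
        ltim[L] = ltii[L] = _LOG0
        lentry = -math.log(L)
        if self.flank_loop > 0:
            lnn = math.log(self.flank_loop)
            lnb = math.log1p(-self.flank_loop)
        else:
            lnn = _LOG0
            lnb = 0.0
        self._kernel_args = (lme, lie, lbg, ltmm, ltmi, ltmd, ltim, ltii,
                             ltdm, ltdd, ltme, ltde, lentry, lnn, lnb,
                             lnn, lnb)
        return self._kernel_args

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        obj = {
            "format": "fhalmine-hmm",
            "version": 1,
            "L": self.L,
            "alphabet": AA,
            "match_emit": self.match_emit.tolist(),
            "insert_emit": self.insert_emit.tolist(),
            "trans": {k: v.tolist() for k, v in self.trans.items()},
            "background": self.background.tolist(),
            "exit_prob": self.exit_prob,
            "flank_loop": self.flank_loop,
            "match_columns": self.match_columns,
            "training_maps": {
                k: [list(p) for p in v] for k, v in self.training_maps.items()
            },
            "calibration": None
            if self.calibration is None
            else {
                "mu": self.calibration.mu,
                "lam": self.calibration.lam,
                "n_decoys": self.calibration.n_decoys,
                "seed": self.calibration.seed,
            },
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "ProfileHmm":
        with open(path) as fh:
            obj = json.load(fh)
        if obj.get("format") != "fhalmine-hmm":
            raise ValueError(f"{path}: not a fhalmine HMM JSON file")
        cal = obj.get("calibration")
        return cls(
            L=obj["L"],
            match_emit=np.array(obj["match_emit"]),
            insert_emit=np.array(obj["insert_emit"]),
            trans={k: np.array(v) for k, v in obj["trans"].items()},
            background=np.array(obj["background"]),
            exit_prob=obj["exit_prob"],
            flank_loop=obj["flank_loop"],
            calibration=None if cal is None else GumbelFit(**cal),
            match_columns=list(obj.get("match_columns", [])),
            training_maps={
                k: [tuple(p) for p in v]
                for k, v in obj.get("training_maps", {}).items()
            },
        )


# ---------------------------------------------------------------------------
# Model construction


def build_hmm(
    msa: Msa,
    occupancy_threshold: float = 0.5,
    pseudocount_weight: float = 1.0,
    exit_prob: float = 0.01,
    flank_loop: float = 0.98,
    background: np.ndarray | None = None,
) -> ProfileHmm:
    """Estimate a profile HMM from a protein MSA.

    Columns whose non-gap occupancy is >= occupancy_threshold become match
    states.  Emissions are (counts + w * background) / (n + w); transition
    bundles use the same rule with a uniform prior over the bundle's
    targets.  Observed I<->D adjacencies (illegal in this architecture)
    are not counted.
    """
    if msa.nrow < 2:
        raise ValueError("need at least 2 MSA rows to build a model")
    if pseudocount_weight <= 0:
        raise ValueError("pseudocount_weight must be positive")
    bg = BACKGROUND if background is None else np.asarray(background, dtype=float)
    rows = [row.upper() for _, row in msa.rows]
    ids = msa.ids
    ncol = msa.ncol
    occupancy = np.array(
        [sum(1 for r in rows if r[c] != "-") / len(rows) for c in range(ncol)]
    )
    match_cols = [c for c in range(ncol) if occupancy[c] >= occupancy_threshold]
    L = len(match_cols)
    if L == 0:
        raise ValueError(
            f"no column reaches occupancy {occupancy_threshold}; cannot build model"
        )
    col_rank = {c: k for k, c in enumerate(match_cols)}
    match_col_set = set(match_cols)

    emit_counts = np.zeros((L, 20))
    # transition counts: bundle target order [to_M, to_I, to_D]
    tM = np.zeros((L, 3))
    tI = np.zeros((L, 2))  # [to_M, to_I]
    tD = np.zeros((L, 2))  # [to_M, to_D]
    training_maps: dict[str, list[tuple[int, int]]] = {}

    for rid, row in zip(ids, rows):
        res_pos = 0
        path: list[tuple[str, int]] = []  # (state, k 1-based)
        cmap: list[tuple[int, int]] = []
        for c, ch in enumerate(row):
            if c in match_col_set:
                k = col_rank[c] + 1
                if ch == "-":
                    path.append(("D", k))
                else:
                    res_pos += 1
                    if ch in AA_INDEX:
                        emit_counts[k - 1, AA_INDEX[ch]] += 1
                    path.append(("M", k))
                    cmap.append((res_pos, k))
            else:
                if ch != "-":
                    res_pos += 1
                    k = 0
                    for s, kk in reversed(path):
                        k = kk
                        break
                    path.append(("I", k))
        training_maps[rid] = cmap
        for (s1, k1), (s2, k2) in zip(path, path[1:]):
            if s1 == "M" and k1 < L:
                if s2 == "M":
                    tM[k1 - 1, 0] += 1
                elif s2 == "I":
                    tM[k1 - 1, 1] += 1
                else:
                    tM[k1 - 1, 2] += 1
            elif s1 == "I" and 1 <= k1 < L:
                if s2 == "M":
                    tI[k1 - 1, 0] += 1
                elif s2 == "I":
                    tI[k1 - 1, 1] += 1
                # I -> D not modelled; skip
            elif s1 == "D" and k1 < L:
                if s2 == "M":
                    tD[k1 - 1, 0] += 1
                elif s2 == "D":
                    tD[k1 - 1, 1] += 1
                # D -> I not modelled; skip

    w = pseudocount_weight
    match_emit = (emit_counts + w * bg) / (
        emit_counts.sum(axis=1, keepdims=True) + w
    )
    trans = {}
    pM = (tM + w / 3) / (tM.sum(axis=1, keepdims=True) + w)
    pI = (tI + w / 2) / (tI.sum(axis=1, keepdims=True) + w)
    pD = (tD + w / 2) / (tD.sum(axis=1, keepdims=True) + w)
    trans["mm"], trans["mi"], trans["md"] = pM[:, 0].copy(), pM[:, 1].copy(), pM[:, 2].copy()
    trans["im"], trans["ii"] = pI[:, 0].copy(), pI[:, 1].copy()
    trans["dm"], trans["dd"] = pD[:, 0].copy(), pD[:, 1].copy()
    for key in ("mm", "mi", "md", "im", "ii", "dm", "dd"):
        trans[key][L - 1] = 0.0

    return ProfileHmm(
        L=L,
        match_emit=match_emit,
        insert_emit=bg.copy(),
        trans=trans,
        background=bg.copy(),
        exit_prob=exit_prob,
        flank_loop=flank_loop,
        match_columns=match_cols,
        training_maps=training_maps,
    )


# ---------------------------------------------------------------------------
# Scoring

_LN2 = math.log(2.0)


def _null_logprob(hmm: ProfileHmm, x: np.ndarray) -> float:
    lbg = np.zeros(21)
    lbg[:20] = np.log(hmm.background)
    return float(lbg[x].sum())


def forward_bits(hmm: ProfileHmm, seq: ProteinRecord) -> float:
    """Forward log-odds score in bits (log2 model-vs-background)."""
    x = encode_protein(seq.residues)
    lp = _dp.hmm_forward(x, *hmm._kernel())
    return (lp - _null_logprob(hmm, x)) / _LN2


def viterbi(hmm: ProfileHmm, seq: ProteinRecord):
    """Best-path score, state path, and residue-to-match-column map.

    Returns (bits, path, cmap): path is a list of (state, k) with state in
    {'N','M','I','D','C'}; cmap lists (1-based residue position, 1-based
    match column) for every residue emitted by a match state.
    """
    x = encode_protein(seq.residues)
    lp, ptrM, ptrI, ptrD, ptrEk, ptrEs, ptrC = _dp.hmm_viterbi(x, *hmm._kernel())
    n = len(x)
    path: list[tuple[str, int]] = []
    cmap: list[tuple[int, int]] = []
    i = n
    # walk C back to the point where E was reached
    while i > 0 and ptrC[i] == 1:
        path.append(("C", 0))
        i -= 1
    k = int(ptrEk[i])
    state = "M" if ptrEs[i] == 1 else "D"
    while True:
        path.append((state, k))
        if state == "M":
            cmap.append((i, k))
            p = ptrM[i, k]
            i -= 1
            if p == 0:
                break
            k -= 1
            state = {1: "M", 2: "I", 3: "D"}[int(p)]
        elif state == "I":
            p = ptrI[i, k]
            i -= 1
            state = "M" if p == 1 else "I"
        else:  # D
            p = ptrD[i, k]
            k -= 1
            state = "M" if p == 1 else "D"
    while i > 0:
        path.append(("N", 0))
        i -= 1
    path.reverse()
    cmap.reverse()
    bits = (lp - _null_logprob(hmm, x)) / _LN2
    return bits, path, cmap


def viterbi_bits(hmm: ProfileHmm, seq: ProteinRecord) -> float:
    return viterbi(hmm, seq)[0]


def hit(hmm: ProfileHmm, seq: ProteinRecord, db_size: int = 1) -> HmmHit:
    """Score one sequence: Forward bits, Viterbi alignment span, E-value
    (requires a calibrated model; math.inf E-value otherwise)."""
    bits = forward_bits(hmm, seq)
    _, _, cmap = viterbi(hmm, seq)
    if cmap:
        ali_start, ali_end = cmap[0][0], cmap[-1][0]
    else:
        ali_start = ali_end = 0
    ev = (
        evalue(hmm.calibration, bits, db_size)
        if hmm.calibration is not None
        else math.inf
    )
    return HmmHit(seq.id, bits, ev, ali_start, ali_end)


# ---------------------------------------------------------------------------
# Sampling and calibration


def sample_sequence(hmm: ProfileHmm, seed: int) -> ProteinRecord:
    """Draw one sequence from the core model (glocal: M1 through ML,
    without local entry/exit truncation or background flanks).
    Reproducible for a given seed."""
    rng = np.random.default_rng(seed)
    out: list[str] = []
    t = hmm.trans
    emit_cdf = np.cumsum(hmm.match_emit, axis=1)
    ins_cdf = np.cumsum(hmm.insert_emit)
    k = 1
    state = "M"
    while True:
        if state == "M":
            out.append(AA[min(int(np.searchsorted(emit_cdf[k - 1], rng.random())), 19)])
            if k == hmm.L:
                break
            u = rng.random()
            if u < t["mm"][k - 1]:
                k += 1
            elif u < t["mm"][k - 1] + t["mi"][k - 1]:
                state = "I"
            else:
                k += 1
                state = "D"
        elif state == "I":
            out.append(AA[min(int(np.searchsorted(ins_cdf, rng.random())), 19)])
            if rng.random() < t["im"][k - 1]:
                k += 1
                state = "M"
        else:  # D
            if k == hmm.L:
                break
            if rng.random() < t["dm"][k - 1]:
                k += 1
                state = "M"
            else:
                k += 1
                state = "D"
    return ProteinRecord(f"sample-{seed}", "".join(out))


def sample_background(background: np.ndarray, length: int,
                      rng: np.random.Generator) -> str:
    idx = rng.choice(20, size=length, p=background)
    return "".join(AA[i] for i in idx)


def codon_background(table: int = 11) -> np.ndarray:
    """Amino-acid frequencies of uniformly drawn sense codons: the
    composition of proteins translated from random DNA, i.e. the null
    population a metagenomic ORF scan actually faces."""
    from Bio.Data import CodonTable

    counts = {a: 0 for a in AA}
    for aa in CodonTable.unambiguous_dna_by_id[table].forward_table.values():
        counts[aa] += 1
    freq = np.array([counts[a] for a in AA], dtype=float)
    return freq / freq.sum()


def calibrate(
    hmm: ProfileHmm,
    n_decoys: int = 200,
    decoy_length: int = 400,
    seed: int = DEFAULT_SEED,
    composition: np.ndarray | None = None,
) -> GumbelFit:
    """Fit a Gumbel null to Forward scores of i.i.d. decoys.

    Decoys are drawn from the model's background by default; pass
    `composition` (e.g. codon_background()) to calibrate against a
    different null population.
    """
    if n_decoys < 100:
        raise ValueError("n_decoys must be >= 100")
    comp = hmm.background if composition is None else np.asarray(composition)
    rng = np.random.default_rng(seed)
    scores = np.empty(n_decoys)
    for i in range(n_decoys):
        decoy = ProteinRecord(f"decoy-{i}", sample_background(
            comp, decoy_length, rng))
        scores[i] = forward_bits(hmm, decoy)
    if np.std(scores) < 1e-9:
        raise ValueError("degenerate decoy score variance; cannot calibrate")
    fit = fit_gumbel(scores)
    return GumbelFit(mu=fit[0], lam=fit[1], n_decoys=n_decoys, seed=seed)


def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Gumbel (max) location/rate for a score sample."""
    loc, scale = stats.gumbel_r.fit(scores)
    return float(loc), float(1.0 / scale)


def evalue(fit: GumbelFit, score: float, db_size: int) -> float:
    """Expected number of >= score decoy hits in a database of db_size."""
    if db_size < 1:
        raise ValueError("db_size must be >= 1")
    expo = -fit.lam * (score - fit.mu)
    if expo > 700:  # survival probability saturates at 1
        return float(db_size)
    return float(db_size * -math.expm1(-math.exp(expo)))
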