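"""Pairwise local alignment, homolog collection, and progressive MSA.

The seed-expansion step of model construction: characterized halogenase
sequences are aligned against a candidate database with exact
Smith-Waterman (BLOSUM62, affine gaps, BLAST-style defaults), database
sequences passing the identity/coverage thresholds are collected, and the
retained set is multiply aligned with a single progressive pass over a
UPGMA guide tree built from 3-mer count-vector distances.

Identity is identical columns over *all* alignment columns (gaps
included); coverage is the aligned fraction of the query (the
characterized reference plays the query role in collection).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from . import _dp
from .seq_io import Msa, ProteinRecord

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_B62_ALPHA = _BLOSUM62.alphabet


def _matrix_for(alphabet_size: int = 26) -> np.ndarray:
    S = np.zeros((128, 128))
    for i, a in enumerate(_B62_ALPHA):
        for j, b in enumerate(_B62_ALPHA):
            S[ord(a), ord(b)] = _BLOSUM62[i, j]
    return S


_S_BY_ORD = _matrix_for()


@dataclass
class HomologSearchConfig:
    id_threshold: float = 0.50
    cov_threshold: float = 0.90
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.id_threshold <= 1 and 0 <= self.cov_threshold <= 1):
            raise ValueError("thresholds must lie in [0, 1]")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")


@dataclass
class PairwiseAlignment:
    query_id: str
    target_id: str
    aligned_query: str
    aligned_target: str
    score: float
    identity: float
    query_coverage: float


def _encode_ord(residues: str) -> np.ndarray:
    for r in residues:
        if r not in _B62_ALPHA:
            raise ValueError(f"residue {r!r} not covered by the substitution matrix")
    return np.frombuffer(residues.encode("ascii"), dtype=np.uint8).astype(np.int64)


def local_align(
    query: ProteinRecord, target: ProteinRecord, cfg: HomologSearchConfig | None = None
) -> PairwiseAlignment:
    """Optimal Smith-Waterman local alignment with affine gaps.

    A gap of length k costs gap_open + k * gap_extend.  Ties prefer the
    end cell with the smallest coordinates, then diagonal > up > left
    during traceback.
    """
    cfg = cfg or HomologSearchConfig()
    q = _encode_ord(query.residues)
    t = _encode_ord(target.residues)
    score, bi, bj, ptrH, ptrE, ptrF = _dp.sw_affine(
        q, t, _S_BY_ORD, cfg.gap_open, cfg.gap_extend
    )
    aq: list[str] = []
    at: list[str] = []
    i, j = bi, bj
    state = 0
    while (i > 0 or j > 0) and not (state == 0 and ptrH[i, j] == 0):
        if state == 0:
            p = ptrH[i, j]
            if p == 1:
                aq.append(query.residues[i - 1])
                at.append(target.residues[j - 1])
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            elif p == 3:
                state = 1
        elif state == 1:  # gap in query: consume target
            aq.append("-")
            at.append(target.residues[j - 1])
            if ptrE[i, j] == 1:
                state = 0
            j -= 1
        else:  # gap in target: consume query
            aq.append(query.residues[i - 1])
            at.append("-")
            if ptrF[i, j] == 1:
                state = 0
            i -= 1
    aligned_query = "".join(reversed(aq))
    aligned_target = "".join(reversed(at))
    ncol = len(aligned_query)
    ident = (
        sum(a == b and a != "-" for a, b in zip(aligned_query, aligned_target)) / ncol
        if ncol
        else 0.0
    )
    qcov = sum(c != "-" for c in aligned_query) / len(query.residues)
    return PairwiseAlignment(
        query_id=query.id,
        target_id=target.id,
        aligned_query=aligned_query,
        aligned_target=aligned_target,
        score=float(score),
        identity=ident,
        query_coverage=qcov,
    )


def collect_homologs(
    refs: list[ProteinRecord],
    database: list[ProteinRecord],
    cfg: HomologSearchConfig | None = None,
) -> list[ProteinRecord]:
    """Retain database sequences meeting the identity AND coverage
    thresholds against at least one reference (reference as query).
    Output deduplicated by id, input order preserved."""
    if not refs:
        raise ValueError("need at least one reference sequence")
    cfg = cfg or HomologSearchConfig()
    kept: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in database:
        if rec.id in seen:
            continue
        for ref in refs:
            aln = local_align(ref, rec, cfg)
            if (
                aln.identity >= cfg.id_threshold
                and aln.query_coverage >= cfg.cov_threshold
            ):
                kept.append(rec)
                seen.add(rec.id)
                break
    return kept


# ---------------------------------------------------------------------------
# Progressive MSA

_GAP_PENALTY_OPEN = 11.0
_GAP_PENALTY_EXT = 1.0


def _kmer_vector(seq: str, k: int = 3) -> Counter:
    return Counter(seq[i : i + k] for i in range(len(seq) - k + 1))


def _kmer_distance(a: Counter, b: Counter) -> float:
    """Cosine distance between k-mer count vectors."""
    keys = set(a) | set(b)
    if not keys:
        return 1.0
    va = np.array([a.get(x, 0) for x in keys], dtype=float)
    vb = np.array([b.get(x, 0) for x in keys], dtype=float)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        return 1.0
    return float(1.0 - va @ vb / (na * nb))


def _profile(rows: list[str]) -> np.ndarray:
    """Column frequency profile over the 26 ordinals used by BLOSUM62.

    Frequencies are relative to the total row count, so mostly-gap
    columns carry proportionally little weight in the sum-of-pairs score
    and gaps preferentially align against them."""
    ncol = len(rows[0])
    prof = np.zeros((ncol, 128))
    for row in rows:
        for c, ch in enumerate(row):
            if ch != "-":
                prof[c, ord(ch)] += 1
    return prof / len(rows)


def _merge(rows1: list[str], rows2: list[str]) -> list[str]:
    p1 = _profile(rows1)
    p2 = _profile(rows2)
    S = p1 @ _S_BY_ORD @ p2.T
    moves, _ = _dp.nw_profile_affine(S, _GAP_PENALTY_OPEN, _GAP_PENALTY_EXT)
    out1 = ["" for _ in rows1]
    out2 = ["" for _ in rows2]
    i = j = 0
    for mv in moves:
        if mv == 1:
            for r, row in enumerate(rows1):
                out1[r] += row[i]
            for r, row in enumerate(rows2):
                out2[r] += row[j]
            i += 1
            j += 1
        elif mv == 2:  # column from profile 1 only
            for r, row in enumerate(rows1):
                out1[r] += row[i]
            for r in range(len(rows2)):
                out2[r] += "-"
            i += 1
        else:
            for r in range(len(rows1)):
                out1[r] += "-"
            for r, row in enumerate(rows2):
                out2[r] += row[j]
            j += 1
    return out1 + out2


def progressive_msa(
    seqs: list[ProteinRecord], cfg: HomologSearchConfig | None = None
) -> Msa:
    """One progressive pass: UPGMA guide tree on 3-mer cosine distances,
    profiles merged leaf-to-root with sum-of-pairs scoring and affine
    gaps.  Row order equals input order; de-gapped rows equal the inputs.
    """
    if not seqs:
        raise ValueError("no sequences to align")
    if len(seqs) == 1:
        import warnings

        warnings.warn("progressive_msa called with a single sequence")
        return Msa([(seqs[0].id, seqs[0].residues)])
    n = len(seqs)
    vecs = [_kmer_vector(s.residues) for s in seqs]
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = _kmer_distance(vecs[i], vecs[j])
    Z = linkage(squareform(dm, checks=False), method="average")
    # clusters: index -> (member input indices, aligned rows)
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i].residues]) for i in range(n)
    }
    nxt = n
    for a, b, _, _ in Z:
        ia, rows_a = clusters.pop(int(a))
        ib, rows_b = clusters.pop(int(b))
        clusters[nxt] = (ia + ib, _merge(rows_a, rows_b))
        nxt += 1
    members, rows = clusters.popitem()[1]
    order = np.argsort(members, kind="stable")
    return Msa([(seqs[members[o]].id, rows[o]) for o in order])
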