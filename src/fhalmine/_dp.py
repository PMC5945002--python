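"""Dynamic-programming kernels (numba-compiled).

Straightforward O(n*m) implementations; the surrounding modules own all
biology and parameterisation.  Log-space HMM recursions use a hand-written
logaddexp to keep the kernels self-contained.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

NEG_INF = -1.0e300


@njit(cache=True)
def _lae(a: float, b: float) -> float:
    if a < b:
        a, b = b, a
    if a <= NEG_INF / 2:
        return a
    return a + math.log1p(math.exp(b - a))


# ---------------------------------------------------------------------------
# Smith-Waterman, affine gaps (gap of length k costs open + k * ext)


@njit(cache=True)
def sw_affine(q, t, S, gap_open, gap_ext):
    """Local alignment DP.

    Returns (score, end_i, end_j, ptrH, ptrE, ptrF) where pointers encode,
    for traceback in priority order diagonal > up > left:
      ptrH: 0 stop, 1 diagonal, 2 up (gap in target), 3 left (gap in query)
      ptrE/ptrF: 1 open from H, 0 extend
    Best cell ties prefer the smallest (i, j).
    """
    n, m = len(q), len(t)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG_INF)  # gap in query (left moves)
    F = np.full((n + 1, m + 1), NEG_INF)  # gap in target (up moves)
    ptrH = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrE = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrF = np.zeros((n + 1, m + 1), dtype=np.int8)
    best = 0.0
    bi, bj = 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            eo = H[i, j - 1] - gap_open - gap_ext
            ee = E[i, j - 1] - gap_ext
            if eo >= ee:
                E[i, j] = eo
                ptrE[i, j] = 1
            else:
                E[i, j] = ee
                ptrE[i, j] = 0
            fo = H[i - 1, j] - gap_open - gap_ext
            fe = F[i - 1, j] - gap_ext
            if fo >= fe:
                F[i, j] = fo
                ptrF[i, j] = 1
            else:
                F[i, j] = fe
                ptrF[i, j] = 0
            diag = H[i - 1, j - 1] + S[q[i - 1], t[j - 1]]
            h = 0.0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if F[i, j] > h:
                h = F[i, j]
                p = 2
            if E[i, j] > h:
                h = E[i, j]
                p = 3
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi, bj = i, j
    return best, bi, bj, ptrH, ptrE, ptrF


# ---------------------------------------------------------------------------
# Global profile-profile alignment with affine gaps (for progressive MSA)


@njit(cache=True)
def nw_profile_affine(S, gap_open, gap_ext):
    """Global affine alignment over a precomputed column-score matrix S
    (n1 x n2).  End gaps are charged.  Returns the traceback as an int8
    array of moves from the start: 1 diagonal, 2 up (gap in profile 2),
    3 left (gap in profile 1)."""
    n, m = S.shape
    H = np.full((n + 1, m + 1), NEG_INF)
    E = np.full((n + 1, m + 1), NEG_INF)
    F = np.full((n + 1, m + 1), NEG_INF)
    ptrH = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrE = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrF = np.zeros((n + 1, m + 1), dtype=np.int8)
    H[0, 0] = 0.0
    for j in range(1, m + 1):
        E[0, j] = -gap_open - gap_ext * j
        H[0, j] = E[0, j]
        ptrH[0, j] = 3
        ptrE[0, j] = 1 if j == 1 else 0
    for i in range(1, n + 1):
        F[i, 0] = -gap_open - gap_ext * i
        H[i, 0] = F[i, 0]
        ptrH[i, 0] = 2
        ptrF[i, 0] = 1 if i == 1 else 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            eo = H[i, j - 1] - gap_open - gap_ext
            ee = E[i, j - 1] - gap_ext
            if eo >= ee:
                E[i, j] = eo
                ptrE[i, j] = 1
            else:
                E[i, j] = ee
                ptrE[i, j] = 0
            fo = H[i - 1, j] - gap_open - gap_ext
            fe = F[i - 1, j] - gap_ext
            if fo >= fe:
                F[i, j] = fo
                ptrF[i, j] = 1
            else:
                F[i, j] = fe
                ptrF[i, j] = 0
            diag = H[i - 1, j - 1] + S[i - 1, j - 1]
            h = diag
            p = 1
            if F[i, j] > h:
                h = F[i, j]
                p = 2
            if E[i, j] > h:
                h = E[i, j]
                p = 3
            H[i, j] = h
            ptrH[i, j] = p
    # traceback
    moves = np.zeros(n + m, dtype=np.int8)
    k = 0
    i, j = n, m
    state = 0  # 0=H, 1=E, 2=F
    while i > 0 or j > 0:
        if state == 0:
            p = ptrH[i, j]
            if p == 1:
                moves[k] = 1
                k += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 1
        elif state == 1:
            opened = ptrE[i, j]
            moves[k] = 3
            k += 1
            j -= 1
            if opened == 1:
                state = 0
        else:
            opened = ptrF[i, j]
            moves[k] = 2
            k += 1
            i -= 1
            if opened == 1:
                state = 0
    return moves[:k][::-1].copy(), H[n, m]


# ---------------------------------------------------------------------------
# Profile HMM Forward / Viterbi (log space, local single-hit architecture)
#
# State layout: N (flank) -> B -> {M_k entry, uniform} ... core ... E -> C
# Arrays are indexed k = 1..L; index 0 is unused padding.


@njit(cache=True)
def hmm_forward(x, lme, lie, lbg, ltmm, ltmi, ltmd, ltim, ltii, ltdm, ltdd,
                ltme, ltde, lentry, lnn, lnb, lcc, lct):
    n = len(x)
    L = lme.shape[0] - 1
    vN = np.full(n + 1, NEG_INF)
    vB = np.full(n + 1, NEG_INF)
    vE = np.full(n + 1, NEG_INF)
    vC = np.full(n + 1, NEG_INF)
    vM = np.full((n + 1, L + 1), NEG_INF)
    vI = np.full((n + 1, L + 1), NEG_INF)
    vD = np.full((n + 1, L + 1), NEG_INF)
    vN[0] = 0.0
    vB[0] = lnb
    for i in range(1, n + 1):
        r = x[i - 1]
        vN[i] = vN[i - 1] + lnn + lbg[r]
        vB[i] = vN[i] + lnb
        for k in range(1, L + 1):
            acc = vB[i - 1] + lentry
            if k > 1:
                acc = _lae(acc, vM[i - 1, k - 1] + ltmm[k - 1])
                acc = _lae(acc, vI[i - 1, k - 1] + ltim[k - 1])
                acc = _lae(acc, vD[i - 1, k - 1] + ltdm[k - 1])
            vM[i, k] = acc + lme[k, r]
            if k < L:
                vI[i, k] = _lae(vM[i - 1, k] + ltmi[k],
                                vI[i - 1, k] + ltii[k]) + lie[r]
            if k > 1:
                vD[i, k] = _lae(vM[i, k - 1] + ltmd[k - 1],
                                vD[i, k - 1] + ltdd[k - 1])
        acc = NEG_INF
        for k in range(1, L + 1):
            acc = _lae(acc, vM[i, k] + ltme[k])
            acc = _lae(acc, vD[i, k] + ltde[k])
        vE[i] = acc
        cc = vE[i]
        if i >= 1:
            cc = _lae(cc, vC[i - 1] + lcc + lbg[r])
        vC[i] = cc
    return vC[n] + lct


@njit(cache=True)
def hmm_viterbi(x, lme, lie, lbg, ltmm, ltmi, ltmd, ltim, ltii, ltdm, ltdd,
                ltme, ltde, lentry, lnn, lnb, lcc, lct):
    """Viterbi DP.  Ties prefer M > D > I (and core over fresh entry).

    Returns (logprob, ptrM, ptrI, ptrD, ptrEk, ptrEs, ptrC) for traceback
    by the caller.  Pointer codes in ptrM: 0 from B, 1 from M, 2 from I,
    3 from D.
    """
    n = len(x)
    L = lme.shape[0] - 1
    vN = np.full(n + 1, NEG_INF)
    vB = np.full(n + 1, NEG_INF)
    vE = np.full(n + 1, NEG_INF)
    vC = np.full(n + 1, NEG_INF)
    vM = np.full((n + 1, L + 1), NEG_INF)
    vI = np.full((n + 1, L + 1), NEG_INF)
    vD = np.full((n + 1, L + 1), NEG_INF)
    ptrM = np.zeros((n + 1, L + 1), dtype=np.int8)
    ptrI = np.zeros((n + 1, L + 1), dtype=np.int8)
    ptrD = np.zeros((n + 1, L + 1), dtype=np.int8)
    ptrEk = np.zeros(n + 1, dtype=np.int64)
    ptrEs = np.zeros(n + 1, dtype=np.int8)  # 1 from M, 3 from D
    ptrC = np.zeros(n + 1, dtype=np.int8)  # 0 from E at i, 1 from C loop
    vN[0] = 0.0
    vB[0] = lnb
    for i in range(1, n + 1):
        r = x[i - 1]
        vN[i] = vN[i - 1] + lnn + lbg[r]
        vB[i] = vN[i] + lnb
        for k in range(1, L + 1):
            # priority on ties: M, D, I, then B entry
            best = NEG_INF
            p = 0
            if k > 1:
                c = vM[i - 1, k - 1] + ltmm[k - 1]
                if c > best:
                    best = c
                    p = 1
                c = vD[i - 1, k - 1] + ltdm[k - 1]
                if c > best:
                    best = c
                    p = 3
                c = vI[i - 1, k - 1] + ltim[k - 1]
                if c > best:
                    best = c
                    p = 2
            c = vB[i - 1] + lentry
            if c > best:
                best = c
                p = 0
            vM[i, k] = best + lme[k, r]
            ptrM[i, k] = p
            if k < L:
                cm = vM[i - 1, k] + ltmi[k]
                ci = vI[i - 1, k] + ltii[k]
                if cm >= ci:
                    vI[i, k] = cm + lie[r]
                    ptrI[i, k] = 1
                else:
                    vI[i, k] = ci + lie[r]
                    ptrI[i, k] = 2
            if k > 1:
                cm = vM[i, k - 1] + ltmd[k - 1]
                cd = vD[i, k - 1] + ltdd[k - 1]
                if cm >= cd:
                    vD[i, k] = cm
                    ptrD[i, k] = 1
                else:
                    vD[i, k] = cd
                    ptrD[i, k] = 3
        beste = NEG_INF
        bk = 0
        bs = 1
        for k in range(1, L + 1):
            c = vM[i, k] + ltme[k]
            if c > beste:
                beste = c
                bk = k
                bs = 1
            c = vD[i, k] + ltde[k]
            if c > beste:
                beste = c
                bk = k
                bs = 3
        vE[i] = beste
        ptrEk[i] = bk
        ptrEs[i] = bs
        ce = vE[i]
        cl = vC[i - 1] + lcc + lbg[r] if i >= 1 else NEG_INF
        if ce >= cl:
            vC[i] = ce
            ptrC[i] = 0
        else:
            vC[i] = cl
            ptrC[i] = 1
    return vC[n] + lct, ptrM, ptrI, ptrD, ptrEk, ptrEs, ptrC
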