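"""Independent brute-force oracles used by the unit and acceptance suites.

These deliberately avoid the package's dynamic-programming code paths:
the HMM oracle sums/maximises over explicitly enumerated state paths in
probability space, and the local-alignment oracle enumerates alignment
operation sequences recursively.
"""

from functools import lru_cache

import numpy as np

from fhalmine.profile_hmm import AA_INDEX


def hmm_path_scores(hmm, residues: str):
    """(forward_bits, viterbi_bits) by explicit path enumeration."""
    x = [AA_INDEX[r] for r in residues]
    n = len(x)
    L = hmm.L
    me = hmm.match_emit
    ie = hmm.insert_emit
    bg = hmm.background
    t = hmm.trans
    mu = hmm.exit_prob
    keep = 1.0 - mu
    p = hmm.flank_loop

    def make(agg):
        @lru_cache(maxsize=None)
        def C(i):
            tot = []
            if i == n:
                tot.append(1.0 - p)
            if i < n:
                tot.append(p * bg[x[i]] * C(i + 1))
            return agg(tot) if tot else 0.0

        def E(i):
            return C(i)

        @lru_cache(maxsize=None)
        def D(k, i):
            if k == L:
                return E(i)
            return agg(
                [t["dm"][k - 1] * M(k + 1, i), t["dd"][k - 1] * D(k + 1, i)]
            )

        @lru_cache(maxsize=None)
        def I(k, i):
            if i >= n:
                return 0.0
            return ie[x[i]] * agg(
                [t["im"][k - 1] * M(k + 1, i + 1), t["ii"][k - 1] * I(k, i + 1)]
            )

        @lru_cache(maxsize=None)
        def M(k, i):
            if i >= n:
                return 0.0
            return me[k - 1][x[i]] * after_M(k, i + 1)

        @lru_cache(maxsize=None)
        def after_M(k, i):
            if k == L:
                return E(i)
            return agg(
                [
                    mu * E(i),
                    keep * t["mm"][k - 1] * M(k + 1, i),
                    keep * t["mi"][k - 1] * I(k, i),
                    keep * t["md"][k - 1] * D(k + 1, i),
                ]
            )

        def B(i):
            return agg([(1.0 / L) * M(k, i) for k in range(1, L + 1)])

        @lru_cache(maxsize=None)
        def N(i):
            tot = [(1.0 - p) * B(i)]
            if i < n:
                tot.append(p * bg[x[i]] * N(i + 1))
            return agg(tot)

        return N(0)

    null = float(np.prod([bg[r] for r in x]))
    fwd = make(sum)
    vit = make(max)
    return np.log2(fwd / null), np.log2(vit / null)


def local_align_score(q: str, t: str, S, gap_open: float, gap_ext: float):
    """Best Smith-Waterman score by exhaustive enumeration of alignment
    operation sequences (exponential; tiny inputs only)."""
    n, m = len(q), len(t)
    best = 0.0
    max_pair = max(max(row.values()) for row in S.values())

    def extend(i, j, score, state):
        nonlocal best
        if score > best:
            best = score
        # bound: even matching every remaining pair cannot beat the best
        if score + max_pair * min(n - i, m - j) <= best:
            return
        if i < n and j < m:
            extend(i + 1, j + 1, score + S[q[i]][t[j]], 0)
        if i < n:
            cost = gap_ext if state == 1 else gap_open + gap_ext
            extend(i + 1, j, score - cost, 1)
        if j < m and state != 1:
            # canonical order: a left-gap never directly follows an up-gap
            cost = gap_ext if state == 2 else gap_open + gap_ext
            extend(i, j + 1, score - cost, 2)

    for i0 in range(n + 1):
        for j0 in range(m + 1):
            extend(i0, j0, 0.0, 0)
    return best


def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """A random unrooted binary tree topology with strictly positive branch
    lengths, returned as (leaf names, distance matrix, bipartition set).

    Built by sequential leaf attachment; distances are exact path sums, so
    the matrix is additive by construction.
    """
    # adjacency over node ids; leaves 0..n-1, internals negative
    names = [f"L{i}" for i in range(n_leaves)]
    adj: dict[int, dict[int, float]] = {0: {}, 1: {}}
    nxt_internal = -1

    def blen():
        return float(rng.uniform(0.1, 1.0))

    adj[0][1] = adj[1][0] = blen()
    edges = [(0, 1)]
    for leaf in range(2, n_leaves):
        a, b = edges[rng.integers(len(edges))]
        w = adj[a].pop(b)
        adj[b].pop(a)
        mid = nxt_internal
        nxt_internal -= 1
        adj[mid] = {}
        split = float(rng.uniform(0.25, 0.75)) * w
        adj[a][mid] = adj[mid][a] = split
        adj[b][mid] = adj[mid][b] = w - split
        adj[leaf] = {}
        adj[leaf][mid] = adj[mid][leaf] = blen()
        edges.remove((a, b))
        edges.extend([(a, mid), (b, mid), (leaf, mid)])

    D = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for dst in range(n_leaves):
            D[src, dst] = dist[dst]

    # bipartitions: cutting each internal-internal or internal-leaf edge
    all_set = frozenset(names)
    anchor = min(all_set)
    parts = set()
    for a, b in edges:
        # side reachable from a without crossing (a, b)
        seen = {a}
        stack = [a]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen and not (u == a and v == b):
                    seen.add(v)
                    stack.append(v)
        side = frozenset(names[i] for i in seen if 0 <= i < n_leaves)
        if anchor in side:
            side = all_set - side
        if 2 <= len(side) <= n_leaves - 2:
            parts.add(side)
    return names, D, parts
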