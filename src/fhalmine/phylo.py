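"""Distance phylogenetics: p-distance, neighbour joining, bootstrap,
and variant A/B classification of halogenase candidates.

Variant A flavin-dependent halogenases act on free substrates, variant B
on carrier-protein-bound substrates; variant B proteins run roughly 70
amino acids shorter.  Candidates are classified by the smallest clade
(bipartition side) that contains them together with references of exactly
one variant; when every such clade is mixed, a length prior with the
70-aa offset decides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .seq_io import Msa

logger = logging.getLogger(__name__)

DEFAULT_BOOTSTRAP_REPS = 1000
DEFAULT_SEED = 1699


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix contains non-finite entries")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < -1e-12):
            raise ValueError("distances must be nonnegative")


class Node:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name=None, length=None, support=None):
        self.name = name
        self.length = length
        self.support = support
        self.children: list[Node] = []
        self.parent: Node | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)


@dataclass
class PhyloTree:
    """Unrooted tree stored with a (trifurcating) root for serialization."""

    root: Node

    def leaves(self) -> list[Node]:
        out = []

        def walk(n):
            if n.is_leaf():
                out.append(n)
            for c in n.children:
                walk(c)

        walk(self.root)
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def internal_edges(self) -> list[Node]:
        """Internal (non-root, non-leaf) nodes; each stands for the edge to
        its parent."""
        out = []

        def walk(n):
            for c in n.children:
                if not c.is_leaf():
                    out.append(c)
                walk(c)

        walk(self.root)
        return out

    def bipartitions(self) -> dict[frozenset, Node]:
        """Non-trivial bipartitions as canonical frozensets (the side not
        containing the lexicographically smallest leaf), mapped to the node
        below the corresponding edge."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        out: dict[frozenset, Node] = {}
        for node in self.internal_edges():
            side = frozenset(l.name for l in PhyloTree(node).leaves())
            if anchor in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                out[side] = node
        return out

    def clades_containing(self, name: str) -> list[frozenset]:
        """Every bipartition side containing the named leaf, smallest first."""
        all_leaves = frozenset(self.leaf_names())
        sides = []
        for part in self.bipartitions():
            comp = all_leaves - part
            side = part if name in part else comp
            sides.append(side)
        sides.sort(key=lambda s: (len(s), tuple(sorted(s))))
        return sides

    def leaf_distances_from(self, name: str) -> dict[str, float]:
        """Path (branch-length) distance from the named leaf to all leaves."""
        target = None
        for l in self.leaves():
            if l.name == name:
                target = l
        if target is None:
            raise ValueError(f"leaf {name!r} not in tree")
        # distance from target to every node by traversal over the
        # undirected tree
        dist: dict[int, float] = {id(target): 0.0}
        stack = [target]
        out: dict[str, float] = {}
        while stack:
            n = stack.pop()
            dn = dist[id(n)]
            if n.is_leaf() and n.name != name:
                out[n.name] = dn
            neighbors = list(n.children)
            if n.parent is not None:
                neighbors.append(n.parent)
            for m in neighbors:
                if id(m) in dist:
                    continue
                edge = n.length if m is n.parent else m.length
                dist[id(m)] = dn + (edge or 0.0)
                stack.append(m)
        return out


# ---------------------------------------------------------------------------
# Distances


def _encode_msa(msa: Msa) -> np.ndarray:
    arr = np.full((msa.nrow, msa.ncol), -1, dtype=np.int8)
    for i, (_, row) in enumerate(msa.rows):
        for c, ch in enumerate(row):
            if ch != "-":
                arr[i, c] = ord(ch)
    return arr


def pdistance_matrix(
    msa: Msa, correction: str = "none", _encoded: np.ndarray | None = None
) -> DistanceMatrix:
    """Pairwise p-distance with pairwise deletion of gapped columns;
    optional Poisson correction -ln(1 - p)."""
    if msa.nrow < 3:
        raise ValueError("need at least 3 sequences for a distance matrix")
    if correction not in ("none", "poisson"):
        raise ValueError(f"unknown correction {correction!r}")
    X = _encode_msa(msa) if _encoded is None else _encoded
    n = X.shape[0]
    present = X >= 0
    d = np.zeros((n, n))
    for i in range(n):
        both = present[i] & present
        comparable = both.sum(axis=1)
        diff = ((X[i] != X) & both).sum(axis=1)
        zero = comparable == 0
        zero[i] = False
        if np.any(zero):
            j = int(np.nonzero(zero)[0][0])
            raise ValueError(
                f"no comparable columns between {msa.ids[i]!r} and {msa.ids[j]!r}"
            )
        with np.errstate(invalid="ignore"):
            d[i] = diff / np.maximum(comparable, 1)
    if correction == "poisson":
        if np.any(d >= 1.0):
            raise ValueError("p-distance of 1 cannot be Poisson-corrected")
        d = -np.log1p(-d)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # exact symmetry against float noise
    return DistanceMatrix(list(msa.ids), d)


# ---------------------------------------------------------------------------
# Neighbour joining


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbour joining with the standard Q criterion.

    Ties are broken by the lowest index pair; negative branch lengths are
    clamped to zero (and logged).  Exact on additive matrices.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    D = dm.d.copy()
    nodes: list[Node] = [Node(name=i) for i in dm.ids]
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            if x < -1e-9:
                logger.info("clamping negative branch length %.3g to 0", x)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        u = Node()
        ni, nj = nodes[i], nodes[j]
        ni.length = clamp(li)
        nj.length = clamp(lj)
        u.add(ni)
        u.add(nj)
        # distances from the new node to the remaining taxa
        newd = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = newd
        D[:, i] = newd
        D[i, i] = 0.0
        nodes[i] = u
        active.remove(j)
    # final three-way join (closed form)
    a, b, c = active
    root = Node()
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = clamp(ln)
        root.add(nodes[idx])
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_support(
    msa: Msa,
    n_reps: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int = DEFAULT_SEED,
    correction: str = "none",
    max_redraws: int = 100,
) -> PhyloTree:
    """Felsenstein bootstrap: support on each internal edge of the
    full-data NJ tree = percentage of column-resampled replicate trees
    containing that bipartition.  Replicates with an incomparable pair are
    redrawn (capped at max_redraws per replicate)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    X = _encode_msa(msa)
    full = nj_tree(pdistance_matrix(msa, correction, _encoded=X))
    parts = full.bipartitions()
    counts = {p: 0 for p in parts}
    rng = np.random.default_rng(seed)
    ncol = msa.ncol
    redraws = 0
    for _ in range(n_reps):
        for attempt in range(max_redraws + 1):
            cols = rng.integers(0, ncol, size=ncol)
            Xb = X[:, cols]
            try:
                dmb = pdistance_matrix(
                    _FakeMsa(msa.ids, ncol), correction, _encoded=Xb
                )
            except ValueError:
                redraws += 1
                continue
            break
        else:
            raise ValueError("replicate redraw cap exceeded")
        rep = nj_tree(dmb)
        for p in rep.bipartitions():
            if p in counts:
                counts[p] += 1
    for p, node in parts.items():
        node.support = round(100.0 * counts[p] / n_reps)
    return full


class _FakeMsa:
    """Shim giving pdistance_matrix ids/ncol for a pre-encoded matrix."""

    def __init__(self, ids, ncol):
        self.ids = list(ids)
        self.ncol = ncol
        self.nrow = len(self.ids)


# ---------------------------------------------------------------------------
# Variant classification


@dataclass
class VariantLengthPrior:
    """Expected A-minus-B protein length difference, with the variant A
    mean length used as the reference point (rebH: 530 aa)."""

    delta_aa: float = 70.0
    mean_len_a: float = 530.0

    def __post_init__(self) -> None:
        if self.delta_aa <= 0:
            raise ValueError("delta_aa must be positive")

    def call(self, query_length: float) -> str:
        mean_b = self.mean_len_a - self.delta_aa
        da = abs(query_length - self.mean_len_a)
        db = abs(query_length - mean_b)
        return "A" if da <= db else "B"


@dataclass
class VariantCall:
    query_id: str
    call: str                     # "A", "B", or "unclassified"
    evidence: str | None          # "clade", "length_prior", "both", or None
    nearest_ref: str | None


def classify_variant(
    tree: PhyloTree,
    refs_a: set[str],
    refs_b: set[str],
    query_id: str,
    query_length: int | None = None,
    length_prior: VariantLengthPrior | None = None,
) -> VariantCall:
    """Assign a candidate to variant A or B.

    The call is the class of the smallest bipartition side containing the
    query together with references of exactly one class.  When pure sides
    of *both* classes contain the query (a query hanging between the two
    reference clades lies on one side of every deep split), the class of
    the patristically nearest reference that shares a pure side with the
    query decides.  When every side is mixed, the length prior decides
    (evidence 'length_prior'); when the clade rule fires and the length
    prior agrees, evidence is 'both'."""
    names = set(tree.leaf_names())
    if query_id not in names:
        raise ValueError(f"query {query_id!r} not in tree")
    refs_a = set(refs_a) & names
    refs_b = set(refs_b) & names
    dists = tree.leaf_distances_from(query_id)

    def nearest(cands: set[str]) -> str | None:
        cands = cands - {query_id}
        return min(cands, key=lambda c: (dists.get(c, np.inf), c)) if cands else None

    pure_a: set[str] = set()   # refs sharing a pure-A side with the query
    pure_b: set[str] = set()
    first_pure: str | None = None
    for side in tree.clades_containing(query_id):
        in_a = side & refs_a
        in_b = side & refs_b
        if in_a and not in_b:
            pure_a |= in_a
            first_pure = first_pure or "A"
        elif in_b and not in_a:
            pure_b |= in_b
            first_pure = first_pure or "B"
    call = None
    if pure_a and pure_b:
        na, nb = nearest(pure_a), nearest(pure_b)
        call = "A" if dists.get(na, np.inf) <= dists.get(nb, np.inf) else "B"
    elif pure_a or pure_b:
        call = first_pure
    if call is not None:
        ev = "clade"
        if query_length is not None and length_prior is not None:
            if length_prior.call(query_length) == call:
                ev = "both"
        return VariantCall(
            query_id, call, ev, nearest(pure_a if call == "A" else pure_b)
        )
    if query_length is not None:
        prior = length_prior or VariantLengthPrior()
        call = prior.call(query_length)
        refs = refs_a if call == "A" else refs_b
        return VariantCall(query_id, call, "length_prior", nearest(refs))
    return VariantCall(query_id, "unclassified", None, None)
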