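"""p-distances, neighbour joining, bootstrap, and variant classification."""

import inspect

import numpy as np
import pytest

from _oracles import random_additive_tree
from fhalmine.phylo import (
    DEFAULT_BOOTSTRAP_REPS,
    DistanceMatrix,
    Node,
    PhyloTree,
    VariantLengthPrior,
    bootstrap_support,
    classify_variant,
    nj_tree,
    pdistance_matrix,
)
from fhalmine.seq_io import Msa


class TestPDistance:
    def test_identical_rows_zero(self):
        msa = Msa([("a", "MKVLW"), ("b", "MKVLW"), ("c", "MKVLW")])
        dm = pdistance_matrix(msa)
        assert np.allclose(dm.d, 0.0)

    def test_three_of_ten_differences(self):
        msa = Msa([
            ("a", "MKVLWDERTG"),
            ("b", "MKVLWAAATG"),  # 3 differences
            ("c", "MKVLWDERTG"),
        ])
        dm = pdistance_matrix(msa)
        assert dm.d[0, 1] == pytest.approx(0.3)

    def test_pairwise_deletion_counting_oracle(self):
        rng = np.random.default_rng(3)
        alpha = "ACDE-"
        for _ in range(10):
            rows = [
                (f"s{i}", "".join(alpha[j] for j in rng.integers(0, 5, 30)))
                for i in range(5)
            ]
            rows = [(i, r if r.replace("-", "") else r[:-1] + "A")
                    for i, r in rows]
            msa = Msa(rows)
            try:
                dm = pdistance_matrix(msa)
            except ValueError:
                continue  # a pair with zero comparable columns
            for i in range(5):
                for j in range(5):
                    ri, rj = rows[i][1], rows[j][1]
                    comp = [
                        (a, b) for a, b in zip(ri, rj) if a != "-" and b != "-"
                    ]
                    want = (
                        sum(a != b for a, b in comp) / len(comp) if comp else 0
                    )
                    if i != j:
                        assert dm.d[i, j] == pytest.approx(want)

    def test_incomparable_pair_names_sequences(self):
        msa = Msa([("a", "A--"), ("b", "--C"), ("c", "ABC"[:3])])
        with pytest.raises(ValueError, match="'a' and 'b'"):
            pdistance_matrix(msa)

    def test_poisson_correction(self):
        msa = Msa([
            ("a", "MKVLWDERTG"),
            ("b", "MKVLWAAATG"),
            ("c", "MKVLWDERTG"),
        ])
        dm = pdistance_matrix(msa, correction="poisson")
        assert dm.d[0, 1] == pytest.approx(-np.log(0.7))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = nj_tree(DistanceMatrix(["A", "B", "C"], d))
        by_name = {l.name: l.length for l in tree.leaves()}
        assert by_name["A"] == pytest.approx((5 + 9 - 10) / 2)
        assert by_name["B"] == pytest.approx((5 + 10 - 9) / 2)
        assert by_name["C"] == pytest.approx((9 + 10 - 5) / 2)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_exact_recovery_of_additive_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 11))
        names, D, parts = random_additive_tree(n, rng)
        tree = nj_tree(DistanceMatrix(names, D))
        assert set(tree.bipartitions()) == parts
        # branch lengths: induced path metric equals the input exactly
        for i, src in enumerate(names):
            got = tree.leaf_distances_from(src)
            for j, dst in enumerate(names):
                if i != j:
                    assert got[dst] == pytest.approx(D[i, j])

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(11)
        names, D, parts = random_additive_tree(7, rng)
        perm = rng.permutation(7)
        tree = nj_tree(
            DistanceMatrix([names[i] for i in perm], D[np.ix_(perm, perm)])
        )
        assert set(tree.bipartitions()) == parts

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b", "c"], d)


class TestBootstrap:
    def test_unanimous_signal_gets_full_support(self):
        rows = [(f"x{i}", "AAAAAAAAAA" + "CCCCCCCCCC") for i in range(3)]
        rows += [(f"y{i}", "CCCCCCCCCC" + "AAAAAAAAAA") for i in range(3)]
        # add within-group variation so distances are informative
        rows[1] = ("x1", "AAAAAAAAAC" + "CCCCCCCCCC")
        rows[4] = ("y1", "CCCCCCCCCA" + "AAAAAAAAAA")
        tree = bootstrap_support(Msa(rows), n_reps=100, seed=5)
        parts = tree.bipartitions()
        xside = frozenset({"x0", "x1", "x2"})
        yside = frozenset({"y0", "y1", "y2"})
        assert xside in parts or yside in parts
        node = parts.get(xside) or parts.get(yside)
        assert node.support == 100

    def test_default_replicates_is_one_thousand(self):
        assert DEFAULT_BOOTSTRAP_REPS == 1000
        sig = inspect.signature(bootstrap_support)
        assert sig.parameters["n_reps"].default == 1000

    def test_support_consistent_across_seeds(self):
        rng = np.random.default_rng(31)
        alpha = "ACDEFG"
        rows = [
            (f"t{i}", "".join(alpha[j] for j in rng.integers(0, 6, 60)))
            for i in range(5)
        ]
        t1 = bootstrap_support(Msa(rows), n_reps=200, seed=1)
        t2 = bootstrap_support(Msa(rows), n_reps=200, seed=2)
        s1 = {p: n.support for p, n in t1.bipartitions().items()}
        s2 = {p: n.support for p, n in t2.bipartitions().items()}
        assert set(s1) == set(s2)
        for p in s1:
            # 99% binomial envelope around the s2 estimate at n=200
            phat = s2[p] / 100
            half = 2.576 * np.sqrt(max(phat * (1 - phat), 0.25 / 200) / 200)
            assert abs(s1[p] / 100 - phat) <= half + 0.01


def _leaf(name):
    return Node(name=name, length=0.1)


def _clade(*names, length=0.2):
    n = Node(length=length)
    for x in names:
        n.add(_leaf(x))
    return n


class TestClassifyVariant:
    def test_query_inside_pure_a_clade(self):
        root = Node()
        a = Node(length=0.3)
        a.add(_clade("A1", "A2"))
        a.add(_leaf("q"))
        root.add(a)
        root.add(_clade("B1", "B2"))
        root.add(_leaf("out"))
        call = classify_variant(
            PhyloTree(root), {"A1", "A2"}, {"B1", "B2"}, "q"
        )
        assert call.call == "A"
        assert call.evidence == "clade"
        assert call.nearest_ref in {"A1", "A2"}

    def test_query_next_to_b_reference(self):
        root = Node()
        b = Node(length=0.2)
        b.add(_leaf("q"))
        b.add(_leaf("B1"))
        root.add(b)
        root.add(_clade("B2", "B3"))
        root.add(_clade("A1", "A2"))
        call = classify_variant(
            PhyloTree(root), {"A1", "A2"}, {"B1", "B2", "B3"}, "q"
        )
        assert call.call == "B"
        assert call.nearest_ref == "B1"

    def test_mixed_clades_fall_back_to_length_prior(self):
        root = Node()
        root.add(_clade("A1", "B1"))
        root.add(_clade("A2", "B2"))
        root.add(_leaf("q"))
        tree = PhyloTree(root)
        call = classify_variant(
            tree, {"A1", "A2"}, {"B1", "B2"}, "q",
            query_length=460, length_prior=VariantLengthPrior(70, 530),
        )
        assert call.call == "B"
        assert call.evidence == "length_prior"
        call_a = classify_variant(
            tree, {"A1", "A2"}, {"B1", "B2"}, "q",
            query_length=530, length_prior=VariantLengthPrior(70, 530),
        )
        assert call_a.call == "A"

    def test_no_references_anywhere_gives_unclassified(self):
        root = Node()
        root.add(_clade("x1", "x2"))
        root.add(_leaf("q"))
        root.add(_leaf("x3"))
        call = classify_variant(
            PhyloTree(root), {"A1", "A2"}, {"B1", "B2"}, "q"
        )
        assert call.call == "unclassified"
        assert call.evidence is None

    def test_absent_query_rejected(self):
        root = Node()
        root.add(_clade("A1", "A2"))
        root.add(_leaf("B1"))
        root.add(_leaf("B2"))
        with pytest.raises(ValueError, match="query"):
            classify_variant(
                PhyloTree(root), {"A1", "A2"}, {"B1", "B2"}, "nope"
            )

    def test_length_prior_validation(self):
        with pytest.raises(ValueError):
            VariantLengthPrior(delta_aa=-1)
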