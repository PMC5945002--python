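"""Profile HMM construction, scoring (vs path enumeration), sampling,
and Gumbel E-value calibration."""

import math

import numpy as np
import pytest
from scipy import stats

from _oracles import hmm_path_scores
from fhalmine.profile_hmm import (
    AA,
    AA_INDEX,
    BACKGROUND,
    GumbelFit,
    ProfileHmm,
    build_hmm,
    calibrate,
    evalue,
    fit_gumbel,
    forward_bits,
    sample_sequence,
    viterbi,
    viterbi_bits,
)
from fhalmine.seq_io import Msa, ProteinRecord


def _single_state_hmm(residue="K", flank_loop=0.0):
    me = np.zeros((1, 20))
    me[0, AA_INDEX[residue]] = 1.0
    return ProfileHmm(
        L=1,
        match_emit=me,
        insert_emit=BACKGROUND.copy(),
        trans={k: np.zeros(1) for k in ("mm", "mi", "md", "im", "ii", "dm", "dd")},
        background=np.full(20, 0.05),
        flank_loop=flank_loop,
    )


class TestBuild:
    def test_identity_msa_gives_consensus_model(self):
        msa = Msa([(f"r{i}", "MKVLGW") for i in range(4)])
        hmm = build_hmm(msa)
        assert hmm.L == 6
        for k, res in enumerate("MKVLGW"):
            assert AA[int(np.argmax(hmm.match_emit[k]))] == res

    def test_laplace_pseudocount_arithmetic(self):
        # column counts {A:3, C:1}, uniform background, weight 20 -> +1 each
        msa = Msa([("r1", "A"), ("r2", "A"), ("r3", "A"), ("r4", "C")])
        hmm = build_hmm(
            msa, pseudocount_weight=20.0, background=np.full(20, 1 / 20)
        )
        assert hmm.match_emit[0, AA_INDEX["A"]] == pytest.approx(4 / 24)
        assert hmm.match_emit[0, AA_INDEX["C"]] == pytest.approx(2 / 24)

    def test_occupancy_threshold_straddle(self):
        # col 0: 3/5 residues (60%) -> match at threshold 0.5
        # col 1: 2/5 residues (40%) -> insert at threshold 0.5
        rows = [
            ("a", "AC"),
            ("b", "A-"),
            ("c", "AC"),
            ("d", "--"),
            ("e", "--"),
        ]
        hmm = build_hmm(Msa(rows), occupancy_threshold=0.5)
        assert hmm.L == 1
        assert hmm.match_columns == [0]

    def test_all_gap_columns_raise(self):
        with pytest.raises(ValueError, match="occupancy"):
            build_hmm(
                Msa([("a", "--"), ("b", "--")]), occupancy_threshold=0.5
            )

    def test_bundles_normalized(self, ref_models):
        hmm = ref_models.hmm_a
        hmm.validate()  # raises on any unnormalized bundle


class TestScoring:
    def test_single_state_closed_form(self):
        hmm = _single_state_hmm("K")
        bits = forward_bits(hmm, ProteinRecord("q", "K"))
        assert bits == pytest.approx(math.log2(20))

    @pytest.mark.parametrize("msa_rows", [
        [("a", "AC"), ("b", "AC")],
        [("a", "ACD"), ("b", "A-D"), ("c", "ACD")],
        [("a", "AD"), ("b", "CD"), ("c", "ADC"[:2])],
        [("a", "A-C"), ("b", "ADC"), ("c", "A-C"), ("d", "CDC")],
    ])
    def test_forward_viterbi_match_path_enumeration(self, msa_rows):
        hmm = build_hmm(Msa(msa_rows))
        assert hmm.L <= 3
        alphabet = "ACD"
        seqs = ["".join(s) for n in range(1, 5)
                for s in __import__("itertools").product(alphabet, repeat=n)]
        for s in seqs:
            rec = ProteinRecord("q", s)
            fo, vo = hmm_path_scores(hmm, s)
            assert forward_bits(hmm, rec) == pytest.approx(fo, abs=1e-8)
            assert viterbi_bits(hmm, rec) == pytest.approx(vo, abs=1e-8)

    def test_forward_dominates_viterbi(self, ref_models):
        rng = np.random.default_rng(2)
        hmm = build_hmm(
            Msa([("a", "MKVLWD"), ("b", "MKVAWD"), ("c", "MKVLWE")])
        )
        for _ in range(100):
            n = int(rng.integers(1, 12))
            s = "".join(AA[i] for i in rng.integers(0, 20, size=n))
            rec = ProteinRecord("q", s)
            assert forward_bits(hmm, rec) >= viterbi_bits(hmm, rec) - 1e-9

    def test_score_ignores_sequence_id(self, ref_models):
        hmm = ref_models.hmm_a
        s = sample_sequence(hmm, 77).residues
        a = forward_bits(hmm, ProteinRecord("one_name", s))
        b = forward_bits(hmm, ProteinRecord("another descriptive id", s))
        assert a == b

    def test_viterbi_identity_on_training_consensus(self):
        msa = Msa([(f"r{i}", "MKVLWDER") for i in range(3)])
        hmm = build_hmm(msa)
        bits, path, cmap = viterbi(hmm, ProteinRecord("q", "MKVLWDER"))
        assert [s for s, _ in path if s in "MID"] == ["M"] * 8
        assert cmap == [(i + 1, i + 1) for i in range(8)]

    def test_inserted_residue_yields_one_insert_state(self):
        msa = Msa([(f"r{i}", "MKVLWDER") for i in range(3)])
        hmm = build_hmm(msa)
        _, path, _ = viterbi(hmm, ProteinRecord("q", "MKVLQWDER"))
        core = [s for s, _ in path if s in "MID"]
        assert core.count("I") == 1
        assert core.count("M") == 8

    def test_x_residue_is_score_neutral(self):
        hmm = build_hmm(Msa([(f"r{i}", "MKVLWDER") for i in range(3)]))
        full = forward_bits(hmm, ProteinRecord("q", "MKVLWDER"))
        with_x = forward_bits(hmm, ProteinRecord("q", "MKVLXDER"))
        assert with_x < full  # lost a matching residue, odds ratio 1 at X


class TestSampling:
    def test_deterministic_model_emits_consensus(self):
        me = np.zeros((4, 20))
        for k, res in enumerate("MKVL"):
            me[k, AA_INDEX[res]] = 1.0
        trans = {k: np.zeros(4) for k in ("mi", "md", "ii", "dd")}
        one = np.array([1.0, 1.0, 1.0, 0.0])
        trans["mm"], trans["im"], trans["dm"] = one, one.copy(), one.copy()
        hmm = ProfileHmm(
            L=4,
            match_emit=me,
            insert_emit=BACKGROUND.copy(),
            trans=trans,
            background=BACKGROUND.copy(),
        )
        assert sample_sequence(hmm, 0).residues == "MKVL"
        assert sample_sequence(hmm, 99).residues == "MKVL"

    def test_same_seed_same_sequence(self, ref_models):
        a = sample_sequence(ref_models.hmm_a, 42)
        b = sample_sequence(ref_models.hmm_a, 42)
        assert a.residues == b.residues

    def test_samples_outscore_their_shuffles(self, ref_models):
        hmm = ref_models.hmm_b
        rng = np.random.default_rng(6)
        sample_scores, shuffle_scores = [], []
        for i in range(40):
            s = sample_sequence(hmm, 1000 + i).residues
            sample_scores.append(forward_bits(hmm, ProteinRecord("s", s)))
            sh = list(s)
            rng.shuffle(sh)
            shuffle_scores.append(
                forward_bits(hmm, ProteinRecord("sh", "".join(sh)))
            )
        assert np.mean(sample_scores) > np.mean(shuffle_scores)
        assert np.median(sample_scores) > np.median(shuffle_scores)


class TestCalibration:
    def test_gumbel_parameter_recovery_within_five_percent(self):
        mu, lam = 5.0, 0.7
        scores = stats.gumbel_r.rvs(
            loc=mu, scale=1 / lam, size=2000,
            random_state=np.random.default_rng(17),
        )
        mu_hat, lam_hat = fit_gumbel(scores)
        assert abs(mu_hat - mu) / mu < 0.05
        assert abs(lam_hat - lam) / lam < 0.05

    def test_evalue_tail_limits(self):
        fit = GumbelFit(mu=0.0, lam=0.7, n_decoys=100, seed=0)
        assert evalue(fit, 1e4, 1000) == pytest.approx(0.0, abs=1e-12)
        assert evalue(fit, -1e4, 1000) == pytest.approx(1000.0)

    def test_evalue_quantile_consistency(self):
        rng = np.random.default_rng(23)
        scores = stats.gumbel_r.rvs(loc=2.0, scale=1.5, size=2000,
                                    random_state=rng)
        mu_hat, lam_hat = fit_gumbel(scores)
        fit = GumbelFit(mu=mu_hat, lam=lam_hat, n_decoys=2000, seed=23)
        q95 = float(np.quantile(scores, 0.95))
        db = 10_000
        e = evalue(fit, q95, db)
        assert 0.03 * db < e < 0.07 * db

    def test_calibrated_model_separates_samples_from_noise(self, hmm_a_calibrated):
        hmm = hmm_a_calibrated
        s = sample_sequence(hmm, 5)
        e_real = evalue(hmm.calibration, forward_bits(hmm, s), 1000)
        assert e_real < 1e-30

    def test_degenerate_decoys_raise(self):
        hmm = _single_state_hmm("K", flank_loop=0.98)
        with pytest.raises(ValueError, match="n_decoys"):
            calibrate(hmm, n_decoys=10, decoy_length=50, seed=1)


class TestSerialization:
    def test_json_round_trip_preserves_scores(self, ref_models, tmp_path):
        hmm = ref_models.hmm_a
        p = tmp_path / "model.json"
        hmm.to_json(p)
        back = ProfileHmm.from_json(p)
        s = sample_sequence(hmm, 8)
        assert forward_bits(back, s) == pytest.approx(forward_bits(hmm, s))
        assert back.match_columns == hmm.match_columns
        assert back.training_maps == hmm.training_maps

    def test_non_model_json_rejected(self, tmp_path):
        p = tmp_path / "x.json"
        p.write_text("{}")
        with pytest.raises(ValueError, match="not a fhalmine HMM"):
            ProfileHmm.from_json(p)
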