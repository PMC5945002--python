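"""The benchmark generator: reference models, planted genes, manifests,
and recovery scoring."""

import numpy as np
import pytest

from conftest import mini_benchmark_config
from fhalmine.annotate import scan_motifs
from fhalmine.orf_finder import reverse_complement, translate
from fhalmine.pipeline import PipelineConfig, run_mining
from fhalmine.profile_hmm import forward_bits, sample_sequence
from fhalmine.seq_io import ProteinRecord
from fhalmine.synthetic_data import (
    BenchmarkConfig,
    PlantedGene,
    TruthManifest,
    brvh_standin,
    make_benchmark,
    make_reference_models,
    score_recovery,
)


class TestReferenceModels:
    def test_model_length_difference_is_70(self, ref_models):
        assert ref_models.hmm_a.L - ref_models.hmm_b.L == 70
        assert ref_models.hmm_a.L == 530

    def test_a_samples_carry_fad_motif_near_n_terminus(self, ref_models):
        hits = 0
        for i in range(200):
            s = sample_sequence(ref_models.hmm_a, 5000 + i)
            found = [
                h
                for h in scan_motifs(s)
                if h.motif == "GxGxxG" and 10 <= h.start <= 30
            ]
            hits += bool(found)
        assert hits >= 190  # >= 95% of draws

    def test_motif_columns_have_low_entropy(self, ref_models):
        me = ref_models.hmm_a.match_emit
        ent = -np.sum(me * np.log(np.maximum(me, 1e-12)), axis=1)
        motif_cols = [15, 17, 20, 82, 274, 276, 278, 279]
        other = [k for k in range(530) if k not in motif_cols]
        assert ent[motif_cols].mean() < ent[other].mean()

    def test_b_family_motif_spacing_differs(self, ref_models):
        # WxWxIP sits ~70 columns earlier in the B family consensus
        row_b = dict(ref_models.msa_b.rows)["refB1"]
        hits = scan_motifs(ProteinRecord("b", row_b))
        w = [h for h in hits if h.motif == "WxWxIP"][0]
        assert w.start == 205


class TestBrvhStandin:
    def test_documented_features(self):
        rec = brvh_standin()
        assert len(rec.residues) == 509
        assert rec.residues[0] == "M"
        assert rec.residues[82] == "K"
        hits = scan_motifs(rec)
        assert [h.start for h in hits if h.motif == "GxGxxG"] == [16]
        assert [h.start for h in hits if h.motif == "WxWxIP"] == [275]

    def test_deterministic(self):
        assert brvh_standin().residues == brvh_standin().residues


class TestMakeBenchmark:
    def test_default_cohort_counts(self, default_benchmark):
        _, contigs, manifest, _ = default_benchmark
        assert len(manifest.entries) == 254
        complete_genes = manifest.count("A", "complete") + manifest.count(
            "B", "complete"
        )
        assert complete_genes == 42
        assert manifest.count("decoy") == 100

    def test_same_seed_identical_output(self):
        cfg = mini_benchmark_config()
        c1, m1 = make_benchmark(cfg)
        c2, m2 = make_benchmark(mini_benchmark_config())
        assert [c.seq for c in c1] == [c.seq for c in c2]
        assert m1.entries == m2.entries

    def test_coordinates_inside_contigs_and_spacing(self, mini_benchmark):
        _, contigs, manifest = mini_benchmark
        lengths = {c.id: len(c) for c in contigs}
        by_contig = {}
        for e in manifest.entries:
            assert 0 <= e.start < e.end <= lengths[e.contig_id]
            by_contig.setdefault(e.contig_id, []).append(e)
        for entries in by_contig.values():
            entries.sort(key=lambda e: e.start)
            for a, b in zip(entries, entries[1:]):
                assert b.start - a.end >= 50

    def test_planted_complete_genes_translate_to_manifest_protein(
        self, mini_benchmark
    ):
        _, contigs, manifest = mini_benchmark
        seqs = {c.id: c.seq for c in contigs}
        for e in manifest.entries:
            if e.completeness != "complete":
                continue
            nt = seqs[e.contig_id][e.start : e.end]
            if e.strand == "-":
                nt = reverse_complement(nt)
            prot = translate(nt)
            assert len(prot) == e.protein_length
            assert prot[0] == "M"
            assert "*" not in prot

    def test_planted_genes_score_far_above_background(
        self, mini_benchmark, ref_models_for_mini
    ):
        _, contigs, manifest = mini_benchmark
        models = ref_models_for_mini
        seqs = {c.id: c.seq for c in contigs}
        rng = np.random.default_rng(2)
        from fhalmine.profile_hmm import sample_background

        decoys = [
            forward_bits(
                models.hmm_a,
                ProteinRecord(
                    "d", sample_background(models.hmm_a.background, 450, rng)
                ),
            )
            for _ in range(50)
        ]
        cutoff = np.quantile(decoys, 0.99)
        for e in manifest.entries:
            if e.completeness != "complete" or e.klass == "decoy":
                continue
            nt = seqs[e.contig_id][e.start : e.end]
            if e.strand == "-":
                nt = reverse_complement(nt)
            prot = ProteinRecord("g", translate(nt))
            hmm = models.hmm_a if e.klass == "A" else models.hmm_b
            assert forward_bits(hmm, prot) > cutoff

    def test_partial_overflow_is_a_sizing_error(self):
        with pytest.raises(ValueError, match="partial"):
            make_benchmark(
                mini_benchmark_config(n_contigs=1, n_partial=3)
            )

    def test_manifest_json_round_trip(self, mini_benchmark, tmp_path):
        _, _, manifest = mini_benchmark
        p = tmp_path / "manifest.json"
        manifest.to_json(p)
        back = TruthManifest.from_json(p)
        assert back.entries == manifest.entries
        assert back.model_seed == manifest.model_seed

    def test_zero_planted_genes_yield_zero_candidates(self, hmm_a_calibrated):
        clean = 0
        complete_free = 0
        for seed in range(20):
            cfg = BenchmarkConfig(
                n_contigs=3,
                contig_length=(5000, 8000),
                n_complete_a=0,
                n_complete_b=0,
                n_partial=0,
                n_decoys=0,
                seed=900 + seed,
            )
            contigs, _ = make_benchmark(cfg)
            report = run_mining(
                PipelineConfig(seed=cfg.seed), contigs=contigs,
                hmm=hmm_a_calibrated,
            )
            clean += report.attrition["evalue_pass"] == 0
            complete_free += report.attrition["complete"] == 0
        assert clean >= 19  # >= 95% of seeds
        assert complete_free == 20


class TestScoreRecovery:
    def _mock_candidates(self, manifest, drop=0):
        class C:
            def __init__(self, e):
                self.contig_id = e.contig_id
                self.start = e.start
                self.end = e.end
                self.strand = e.strand
                self.passed_evalue = True
                self.complete = e.completeness == "complete" and e.klass != "decoy"
                self.variant = e.klass if e.klass in "AB" else None

        picked = [e for e in manifest.entries if e.klass != "decoy"]
        return [C(e) for e in picked[: len(picked) - drop]]

    def test_perfect_report_scores_one(self, mini_benchmark):
        _, _, manifest = mini_benchmark
        res = score_recovery(self._mock_candidates(manifest), manifest)
        for key, val in res["recall"].items():
            if val is not None:
                assert val == 1.0
        assert res["complete_recall"] == 1.0
        assert res["decoy_false_positives"] == 0
        for v in res["precision"].values():
            assert v in (None, 1.0)

    def test_missing_genes_lower_recall(self):
        entries = [
            PlantedGene("c1", i * 2000, i * 2000 + 1500, "+", "A", "complete",
                        "hmmA", 499)
            for i in range(10)
        ]
        manifest = TruthManifest(entries, seed=1)
        res = score_recovery(
            self._mock_candidates(manifest, drop=1), manifest
        )
        assert res["recall"][("A", "complete")] == pytest.approx(0.9)

    def test_unknown_contig_rejected_when_ids_given(self, mini_benchmark):
        _, contigs, manifest = mini_benchmark
        cands = self._mock_candidates(manifest)
        cands[0].contig_id = "nonexistent"
        with pytest.raises(ValueError, match="not in the benchmark"):
            score_recovery(cands, manifest,
                           contig_ids={c.id for c in contigs})
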