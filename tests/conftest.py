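import numpy as np
import pytest

from fhalmine.pipeline import PipelineConfig, run_mining
from fhalmine.profile_hmm import calibrate, codon_background
from fhalmine.synthetic_data import (
    BenchmarkConfig,
    make_benchmark,
    make_reference_models,
)


@pytest.fixture(scope="session")
def ref_models():
    """Small-seed synthetic variant A/B reference families."""
    return make_reference_models(seed=7)


@pytest.fixture(scope="session")
def hmm_a_calibrated(ref_models):
    hmm = ref_models.hmm_a
    if hmm.calibration is None:
        hmm.calibration = calibrate(
            hmm, n_decoys=200, decoy_length=150, seed=11,
            composition=codon_background(),
        )
    return hmm


def mini_benchmark_config(**overrides):
    base = dict(
        n_contigs=6,
        contig_length=(5000, 9000),
        n_complete_a=4,
        n_complete_b=2,
        n_partial=4,
        n_decoys=6,
        seed=202,
    )
    base.update(overrides)
    return BenchmarkConfig(**base)


@pytest.fixture(scope="session")
def mini_benchmark():
    cfg = mini_benchmark_config()
    contigs, manifest = make_benchmark(cfg)
    return cfg, contigs, manifest


@pytest.fixture(scope="session")
def ref_models_for_mini(mini_benchmark):
    _, _, manifest = mini_benchmark
    return make_reference_models(manifest.model_seed)


@pytest.fixture(scope="session")
def default_benchmark():
    """The package's default study conditions (seed 1699; 42 complete
    genes among 254 planted elements)."""
    cfg = BenchmarkConfig()
    contigs, manifest = make_benchmark(cfg)
    models = make_reference_models(manifest.model_seed)
    return cfg, contigs, manifest, models


@pytest.fixture(scope="session")
def default_report(default_benchmark):
    """Full mining run on the default benchmark, shared across tests."""
    cfg, contigs, manifest, models = default_benchmark
    pcfg = PipelineConfig(seed=cfg.seed)
    report = run_mining(
        pcfg,
        contigs=contigs,
        hmm=models.hmm_a,
        refs_a=models.msa_a.degapped(),
        refs_b=models.msa_b.degapped(),
        anchors=[("refA1", 83, "K")],
    )
    return report, manifest
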