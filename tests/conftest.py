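"""Shared fixtures: small synthetic cohorts and a fitted pipeline."""

import numpy as np
import pytest

from netens.cohort_io import RunConfig
from netens.fragments import enumerate_fragments
from netens.preprocess import prepare_cohort
from netens.sampler import sample_ensemble
from netens.synthdata import generate_cohort, generate_ground_truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_gt():
    """Compact ground truth: 6 SNPs, 8 transcripts, 2 planted causes."""
    return generate_ground_truth(
        n_snps=6, n_genes=8, n_planted=2, rng=np.random.default_rng(7)
    )


@pytest.fixture(scope="session")
def small_cohort(small_gt):
    return generate_cohort(small_gt, n_subjects=80, rng=np.random.default_rng(8))


@pytest.fixture(scope="session")
def small_ready(small_cohort):
    """Modeling-ready form of the small cohort (QC'd, transformed)."""
    ready, _ = prepare_cohort(small_cohort, maf_min=0.01)
    return ready


@pytest.fixture(scope="session")
def small_config():
    return RunConfig(seed=11, ensemble_size=64, n_chains=2, fragments_per_child=8)


@pytest.fixture(scope="session")
def small_library(small_ready, small_config):
    return enumerate_fragments(small_ready, small_config)


@pytest.fixture(scope="session")
def small_ensemble(small_library, small_config):
    return sample_ensemble(small_library, small_config)


@pytest.fixture(scope="session")
def null_trial():
    """Full pipeline on a global-null cohort (no transcript -> phenotype
    edges): 100 genes, 100 subjects, fixed seeds.  Returns (ensemble,
    modeling cohort, trial result)."""
    from netens.trial import run_trial

    gt = generate_ground_truth(
        n_genes=100, n_planted=0, rng=np.random.default_rng(100)
    )
    cohort = generate_cohort(gt, n_subjects=100, rng=np.random.default_rng(101))
    ready, _ = prepare_cohort(cohort)
    cfg = RunConfig(seed=3, ensemble_size=64, n_chains=2)
    library = enumerate_fragments(ready, cfg)
    ensemble = sample_ensemble(library, cfg)
    result = run_trial(ensemble, ready, n_replicates=30, seed=4)
    return ensemble, ready, result
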