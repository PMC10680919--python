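"""Shared fixtures: small synthetic studies generated at test time."""

import numpy as np
import pytest
from threadpoolctl import threadpool_limits

import emosig as es


@pytest.fixture(autouse=True, scope="session")
def _single_threaded_blas():
    """Pin BLAS to one thread so decompositions are bit-reproducible."""
    with threadpool_limits(limits=1):
        yield


@pytest.fixture(scope="session")
def noiseless_truth():
    """8 subjects, 200 voxels, no noise/offsets/mixing: exact recovery regime."""
    return es.SyntheticTruth(n_subjects=8, n_voxels=200, noise_sd=0.0,
                             subject_sd=0.0, mixing=0.0, seed=3)


@pytest.fixture(scope="session")
def noiseless_maps(noiseless_truth):
    return es.gen_beta_maps(noiseless_truth, seed=4)


@pytest.fixture(scope="session")
def fixture_truth():
    """Default-noise fixture at desk scale: 20 subjects, 500 voxels."""
    return es.SyntheticTruth(n_subjects=20, n_voxels=500, seed=11)


@pytest.fixture(scope="session")
def fixture_maps(fixture_truth):
    gt = es.gen_beta_maps(fixture_truth, condition="ground_truth", seed=21)
    inf = es.gen_beta_maps(fixture_truth, condition="inference", seed=22)
    return {"ground_truth": gt, "inference": inf}


@pytest.fixture(scope="session")
def fixture_models(fixture_maps):
    return {cond: es.fit_signature(m, seed=0) for cond, m in fixture_maps.items()}


@pytest.fixture(scope="session")
def validation_maps(fixture_truth):
    gt = es.gen_beta_maps(fixture_truth, condition="ground_truth",
                          effect_scale=0.6, modality="audio+visual", seed=31)
    inf = es.gen_beta_maps(fixture_truth, condition="inference",
                           effect_scale=0.6, modality="audio+visual", seed=32)
    return {"ground_truth": gt, "inference": inf}


@pytest.fixture()
def target_series():
    return es.gen_target_ratings(120.0, seed=1)
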