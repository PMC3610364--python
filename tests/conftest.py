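"""Shared fixtures: small synthetic cohorts and fast feature configuration."""

import numpy as np
import pytest

from vagfusion import CohortParams, FeatureConfig, generate_synthetic_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort_params():
    """Reduced-length cohort for fast tests (MP on 1024 samples)."""
    return CohortParams(n_normal=8, n_abnormal=6, n_samples=1024, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_cohort_params):
    return generate_synthetic_cohort(small_cohort_params)


@pytest.fixture(scope="session")
def feature_config():
    return FeatureConfig()


@pytest.fixture(scope="session")
def blobs():
    """Well-separated Gaussian blobs: trivially separable 2-class data."""
    gen = np.random.default_rng(7)
    n = 10
    a = gen.normal(loc=(-3.0, -3.0), scale=0.3, size=(n, 2))
    b = gen.normal(loc=(3.0, 3.0), scale=0.3, size=(n, 2))
    X = np.vstack([a, b])
    y = np.concatenate([-np.ones(n), np.ones(n)])
    return X, y
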