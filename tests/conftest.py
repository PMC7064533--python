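import numpy as np
import pandas as pd
import pytest

from osteomir import ExpressionMatrix, SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def cohort():
    """One seeded default cohort shared by read-only tests."""
    return simulate_cohort(SimulationConfig(seed=11))


def make_matrix(values, feature_ids=None, sample_ids=None, space="log2norm"):
    values = np.asarray(values, dtype=float)
    feature_ids = feature_ids or [f"f{i + 1}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=feature_ids, columns=sample_ids), space)


def pattern_blobs(rng, n_features=8, per_blob=10, separation=10.0, noise_sd=1.0):
    """Two sample groups with opposite feature patterns.

    Centered-correlation distance ignores per-sample additive shifts, so
    separation must live in the feature pattern: blob centroids are
    +/- separation/2 alternating across features.
    """
    mu = np.resize([separation / 2.0, -separation / 2.0], n_features)
    left = mu[:, None] + rng.normal(0.0, noise_sd, (n_features, per_blob))
    right = -mu[:, None] + rng.normal(0.0, noise_sd, (n_features, per_blob))
    return make_matrix(np.hstack([left, right]))
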