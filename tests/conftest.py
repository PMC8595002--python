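import numpy as np
import pytest

from mieeg import SimulationConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """2 subjects x 2 classes x 5 trials, 350 samples x 3 channels."""
    cfg = SimulationConfig(n_subjects=2, trials_per_class_per_subject=5,
                           seed=99)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    from mieeg import extract_feature_matrix
    return extract_feature_matrix(small_dataset)


@pytest.fixture(scope="session")
def blob_data():
    """Two well-separated Gaussian blobs in 95-D, labels {1, 2}."""
    rng = np.random.default_rng(7)
    n = 60
    X = rng.normal(size=(2 * n, 95))
    X[:n, :5] += 8.0
    y = np.array([1] * n + [2] * n)
    perm = rng.permutation(2 * n)
    return X[perm], y[perm]
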