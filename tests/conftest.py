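import numpy as np
import pytest

from s3seg.data import FeatureMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_features(n, d, seed=0, scale=1.0):
    r = np.random.default_rng(seed)
    return FeatureMatrix(scale * r.normal(size=(n, d)),
                         [f"s{i}" for i in range(n)])


def separable_2d(n_per_class, gap, seed):
    """Two well-separated 2-D blobs with +-1 labels (linearly separable)."""
    r = np.random.default_rng(seed)
    pos = r.normal(size=(n_per_class, 2)) * 0.5 + (gap / 2.0, 0.0)
    neg = r.normal(size=(n_per_class, 2)) * 0.5 - (gap / 2.0, 0.0)
    X = np.vstack([pos, neg])
    y = np.concatenate([np.ones(n_per_class), -np.ones(n_per_class)])
    fm = FeatureMatrix(X, [f"s{i}" for i in range(2 * n_per_class)])
    return fm, y
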