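import numpy as np
import pytest

from leafosr.core import FeatureTable, KernelSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def meb_table():
    """Three points whose minimal enclosing ball is center (1,0), R=1."""
    return FeatureTable(
        ids=["a", "b", "c"],
        labels=["x", "x", "x"],
        X=np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 1.0]]),
    )


@pytest.fixture
def linear():
    return KernelSpec("linear")


@pytest.fixture
def rbf_half():
    return KernelSpec("rbf", 0.5)


def make_clusters(centers, per_class, noise_sd, seed, labels=None):
    """Small labeled Gaussian-cluster table for framework tests."""
    rng = np.random.default_rng(seed)
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    k, d = centers.shape
    labels = labels or [f"c{i}" for i in range(k)]
    ids, labs, rows = [], [], []
    for i in range(k):
        rows.append(centers[i] + rng.standard_normal((per_class, d)) * noise_sd)
        ids += [f"{labels[i]}-{j}" for j in range(per_class)]
        labs += [labels[i]] * per_class
    return FeatureTable(ids=ids, labels=labs, X=np.vstack(rows))
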