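import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import coextree as ct

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_distance_matrix(rng, n, low=0.0, high=2.0):
    """Random symmetric distance matrix with zero diagonal."""
    a = rng.uniform(low, high, size=(n, n))
    d = (a + a.T) / 2
    np.fill_diagonal(d, 0.0)
    return ct.DistanceMatrix([f"L{i:02d}" for i in range(n)], d)


@pytest.fixture
def three_leaf_tree():
    """The hand-worked UPGMA example: d(A,B)=2, d(A,C)=d(B,C)=8."""
    d = np.array([[0.0, 2.0, 8.0], [2.0, 0.0, 8.0], [8.0, 8.0, 0.0]])
    return ct.upgma(ct.DistanceMatrix(["A", "B", "C"], d))


@pytest.fixture
def module_data():
    """Small planted-module matrix shared by clade/enrichment tests."""
    m, modules = ct.make_module_matrix(
        n_modules=3, genes_per_module=10, n_background=30, n_samples=100,
        within_r=0.9, seed=7,
    )
    return m, modules
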