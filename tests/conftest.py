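import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ripnet import AdjacencyMatrix

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def adjacency_from_edges(n, edges, ids=None):
    A = np.zeros((n, n))
    for a, b in edges:
        A[a, b] = A[b, a] = 1.0
    return AdjacencyMatrix(A, ids or [f"n{i}" for i in range(n)])


def random_adjacency(rng, n, p=0.3, require_edge=True):
    """Random Erdos-Renyi binary adjacency; resamples until it has an edge."""
    while True:
        U = rng.random((n, n))
        A = np.triu((U < p).astype(float), k=1)
        A = A + A.T
        if not require_edge or A.sum() > 0:
            return AdjacencyMatrix(A, [f"n{i}" for i in range(n)])


@pytest.fixture
def two_triangles():
    """Two disjoint 3-cliques: the canonical Q = 0.5 example."""
    return adjacency_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])


@pytest.fixture
def k4():
    return adjacency_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])


@pytest.fixture
def path3():
    return adjacency_from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def rng():
    return np.random.default_rng(20160509)
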