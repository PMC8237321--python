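import numpy as np
import pytest

from clustval import VertexPartition, WeightedGraph
from clustval.fixtures import binary_random, triangle, two_cliques, wsbm_small


@pytest.fixture
def unit_triangle():
    return triangle(weights=(1.0, 1.0, 1.0))


@pytest.fixture
def weighted_triangle():
    # weights ab=1, bc=2, ac=3
    return triangle(weights=(1.0, 2.0, 3.0))


@pytest.fixture
def cliques():
    return two_cliques(k=5, bridge=1.0)


def random_weighted_graph(rng, n=12, p=0.4, upper_bound=None, binary=False):
    """Connected-ish random graph with uniform(0.1, 1) weights."""
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                w = 1.0 if binary else 0.1 + 0.9 * rng.random()
                edges[(i, j)] = w
    if not edges:
        edges[(0, 1)] = 1.0
    return WeightedGraph([str(v) for v in range(n)], edges, upper_bound)


def random_partition(rng, n, k):
    labels = rng.integers(0, k, size=n)
    return VertexPartition(labels)
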