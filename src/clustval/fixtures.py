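"""Deterministic toy graphs used across the test suite and examples."""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np

from .graph_core import VertexPartition, WeightedGraph
from . import wsbm as _wsbm

__all__ = ["make_fixture"]


def triangle(weights: Sequence[float] = (1.0, 2.0, 3.0), upper_bound=None):
    """Triangle a-b-c with weights (ab, bc, ac)."""
    wab, wbc, wac = weights
    return WeightedGraph.from_edges(
        [("a", "b", wab), ("b", "c", wbc), ("a", "c", wac)],
        upper_bound=upper_bound,
    )


def two_cliques(k: int = 5, bridge: float = 1.0, weight: float = 1.0):
    """Two k-cliques joined by one bridge edge, plus the planted split."""
    triples = []
    for block, offset in ((0, 0), (1, k)):
        for i in range(k):
            for j in range(i + 1, k):
                triples.append((str(offset + i), str(offset + j), weight))
    triples.append(("0", str(k), bridge))
    g = WeightedGraph.from_edges(triples)
    truth = VertexPartition([0] * k + [1] * k, names=g.names)
    return g, truth


def wsbm_small(
    sizes: Tuple[int, ...] = (10, 10), lam: float = 20.0, seed: int = 0
):
    """Small two-block benchmark sample (strong planted structure)."""
    k = len(sizes)
    e = np.full((k, k), 0.05)
    np.fill_diagonal(e, 0.05 * lam)
    spec = _wsbm.WSBMSpec(tuple(sizes), e)
    return _wsbm.sample(spec, seed=seed)


def binary_random(n: int = 20, p: float = 0.2, seed: int = 0):
    """Erdos-Renyi 0/1 graph (weights all 1)."""
    rng = np.random.default_rng(seed)
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges[(i, j)] = 1.0
    return WeightedGraph([str(v) for v in range(n)], edges)


_KINDS = {
    "triangle": triangle,
    "two_cliques": two_cliques,
    "wsbm_small": wsbm_small,
    "binary_random": binary_random,
}


def make_fixture(kind: str, **params):
    """Build one of the named deterministic toy inputs."""
    try:
        fn = _KINDS[kind]
    except KeyError:
        raise KeyError(
            f"unknown fixture {kind!r}; available: {sorted(_KINDS)}"
        ) from None
    return fn(**params)
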