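"""Clustering-algorithm adapters.

The assessment machinery is backend-agnostic: anything callable as
``(graph, seed) -> VertexPartition`` can be evaluated.  The built-in
registry wraps five classic community-detection algorithms from igraph
(Louvain, leading eigenvector, label propagation, Walktrap, spin-glass);
igraph draws its random numbers from Python's ``random`` module, so
seeding the call makes stochastic backends reproducible.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Callable, Dict, Optional

from .graph_core import VertexPartition, WeightedGraph

__all__ = [
    "AlgorithmAdapter",
    "AlgorithmNotApplicable",
    "ADAPTERS",
    "get_adapter",
    "cluster",
]


class AlgorithmNotApplicable(RuntimeError):
    """The algorithm cannot run on this graph (e.g. spin-glass needs a
    connected graph)."""


@dataclass(frozen=True)
class AlgorithmAdapter:
    """Named clustering backend."""

    name: str
    invoke: Callable  # (igraph.Graph) -> membership list
    stochastic: bool
    backend: str

    def __call__(
        self, g: WeightedGraph, seed: Optional[int] = None
    ) -> VertexPartition:
        ig = g.to_igraph()
        if seed is not None:
            random.seed(seed)
        membership = self.invoke(ig)
        if len(membership) != g.n:
            raise AlgorithmNotApplicable(
                f"{self.name} did not label every vertex"
            )
        return VertexPartition(membership, names=g.names)


def _louvain(ig):
    return ig.community_multilevel(weights="weight").membership


def _leading_eigenvector(ig):
    return ig.community_leading_eigenvector(weights="weight").membership


def _label_propagation(ig):
    return ig.community_label_propagation(weights="weight").membership


def _walktrap(ig):
    return ig.community_walktrap(weights="weight").as_clustering().membership


def _spinglass(ig):
    if not ig.is_connected():
        raise AlgorithmNotApplicable("spin-glass requires a connected graph")
    return ig.community_spinglass(weights="weight").membership


ADAPTERS: Dict[str, AlgorithmAdapter] = {
    a.name: a
    for a in [
        AlgorithmAdapter("louvain", _louvain, True, "igraph.community_multilevel"),
        AlgorithmAdapter(
            "leading_eigenvector",
            _leading_eigenvector,
            False,
            "igraph.community_leading_eigenvector",
        ),
        AlgorithmAdapter(
            "label_propagation",
            _label_propagation,
            True,
            "igraph.community_label_propagation",
        ),
        AlgorithmAdapter("walktrap", _walktrap, False, "igraph.community_walktrap"),
        AlgorithmAdapter("spinglass", _spinglass, True, "igraph.community_spinglass"),
    ]
}


def get_adapter(name: str) -> AlgorithmAdapter:
    try:
        return ADAPTERS[name]
    except KeyError:
        raise KeyError(
            f"unknown algorithm {name!r}; registered: {sorted(ADAPTERS)}"
        ) from None


def cluster(
    g: WeightedGraph, algorithm: str = "louvain", seed: Optional[int] = None
) -> VertexPartition:
    """Cluster ``g`` with a registered algorithm."""
    return get_adapter(algorithm)(g, seed=seed)
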