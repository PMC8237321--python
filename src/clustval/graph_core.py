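"""Weighted-graph data model, file I/O, and single-pass cluster aggregates.

The container is deliberately minimal: an undirected simple graph with
strictly positive edge weights (weight 0 means "no edge"), an optional
natural upper bound on weights (e.g. 1 for correlation networks), and
string vertex names mapped to dense 0-based integer ids.  All quantities
that the community scoring functions consume — internal/boundary weight
sums and (restricted) vertex strengths — are computed in one pass over
the edge list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "WeightedGraph",
    "VertexPartition",
    "ClusterAggregates",
    "read_graph",
    "read_membership",
    "write_membership",
    "cluster_aggregates",
]


class GraphError(ValueError):
    """Raised on malformed graph input (self-loops, negative weights...)."""


def _edge_key(i: int, j: int) -> Tuple[int, int]:
    return (i, j) if i < j else (j, i)


class WeightedGraph:
    """Undirected weighted graph with optional weight upper bound.

    Parameters
    ----------
    names
        Vertex names in id order.  Ids are dense, 0-based.
    edges
        Mapping ``(i, j) -> weight`` with ``i < j`` and weight > 0.
    upper_bound
        Optional natural cap on edge weights (weights must not exceed it).
    """

    def __init__(
        self,
        names: Sequence[str],
        edges: Dict[Tuple[int, int], float],
        upper_bound: Optional[float] = None,
    ):
        self.names: List[str] = [str(x) for x in names]
        self.index: Dict[str, int] = {v: i for i, v in enumerate(self.names)}
        if len(self.index) != len(self.names):
            raise GraphError("duplicate vertex names")
        n = len(self.names)
        self.upper_bound = None if upper_bound is None else float(upper_bound)
        if self.upper_bound is not None and self.upper_bound <= 0:
            raise GraphError("upper_bound must be positive")
        self._edges: Dict[Tuple[int, int], float] = {}
        self._adj: List[Dict[int, float]] = [dict() for _ in range(n)]
        for (i, j), w in edges.items():
            i, j = int(i), int(j)
            if i == j:
                raise GraphError(f"self-loop on vertex {self.names[i]!r}")
            if not (0 <= i < n and 0 <= j < n):
                raise GraphError("edge endpoint out of range")
            w = float(w)
            if w < 0:
                raise GraphError(
                    f"negative weight {w} on edge "
                    f"({self.names[i]!r}, {self.names[j]!r}); "
                    "negative weights are not supported"
                )
            if w == 0:
                continue
            if self.upper_bound is not None and w > self.upper_bound + 1e-12:
                raise GraphError(
                    f"weight {w} exceeds upper bound {self.upper_bound}"
                )
            key = _edge_key(i, j)
            if key in self._edges:
                raise GraphError("duplicate edge in constructor")
            self._edges[key] = w
            self._adj[i][j] = w
            self._adj[j][i] = w

    # -- basic accessors ------------------------------------------------

    @property
    def n(self) -> int:
        """Number of vertices."""
        return len(self.names)

    @property
    def m(self) -> int:
        """Number of edges (positive-weight pairs)."""
        return len(self._edges)

    @property
    def total_weight(self) -> float:
        """Sum of all edge weights (the weighted size of the graph)."""
        return float(sum(self._edges.values()))

    def weight(self, u: int, v: int) -> float:
        """Weight of edge (u, v); 0 when the vertices are not adjacent."""
        return self._adj[u].get(v, 0.0)

    def neighbors(self, u: int) -> Dict[int, float]:
        return self._adj[u]

    def edges(self) -> Iterable[Tuple[int, int, float]]:
        for (i, j), w in self._edges.items():
            yield i, j, w

    def edge_dict(self) -> Dict[Tuple[int, int], float]:
        return dict(self._edges)

    def weights_array(self) -> np.ndarray:
        return np.fromiter(self._edges.values(), dtype=float, count=self.m)

    def strengths(self) -> np.ndarray:
        """Weighted degree d~(u) of every vertex."""
        s = np.zeros(self.n)
        for (i, j), w in self._edges.items():
            s[i] += w
            s[j] += w
        return s

    def degrees(self) -> np.ndarray:
        """Unweighted degree d(u) of every vertex."""
        return np.array([len(a) for a in self._adj], dtype=int)

    def median_degree(self) -> float:
        return float(np.median(self.degrees()))

    def median_strength(self) -> float:
        return float(np.median(self.strengths()))

    @property
    def is_binary(self) -> bool:
        """True when every weight equals 1 (0/1 graph)."""
        return all(w == 1.0 for w in self._edges.values())

    @property
    def max_weight(self) -> float:
        return max(self._edges.values()) if self._edges else 0.0

    @property
    def density(self) -> float:
        pairs = self.n * (self.n - 1) / 2
        return self.m / pairs if pairs else 0.0

    # -- constructors ---------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        triples: Iterable[Tuple[str, str, float]],
        upper_bound: Optional[float] = None,
        names: Optional[Sequence[str]] = None,
    ) -> "WeightedGraph":
        """Build from (u, v, w) name triples; duplicate pairs sum weights."""
        order: List[str] = list(names) if names is not None else []
        index = {v: i for i, v in enumerate(order)}
        edges: Dict[Tuple[int, int], float] = {}
        for u, v, w in triples:
            u, v = str(u), str(v)
            w = float(w)
            if w < 0:
                raise GraphError(f"negative weight {w} on edge ({u!r}, {v!r})")
            if u == v:
                raise GraphError(f"self-loop on vertex {u!r}")
            for x in (u, v):
                if x not in index:
                    index[x] = len(order)
                    order.append(x)
            key = _edge_key(index[u], index[v])
            edges[key] = edges.get(key, 0.0) + w
        return cls(order, edges, upper_bound=upper_bound)

    @classmethod
    def complete(
        cls,
        n: int,
        weights: Optional[np.ndarray] = None,
        upper_bound: Optional[float] = None,
    ) -> "WeightedGraph":
        """Complete graph on ``n`` vertices; unit weights by default."""
        names = [str(i) for i in range(n)]
        edges = {}
        k = 0
        for i in range(n):
            for j in range(i + 1, n):
                w = 1.0 if weights is None else float(weights[k])
                edges[(i, j)] = w
                k += 1
        return cls(names, edges, upper_bound=upper_bound)

    def scaled(self, phi: float) -> "WeightedGraph":
        """Graph with every weight multiplied by ``phi`` > 0."""
        if phi <= 0:
            raise GraphError("scale factor must be positive")
        ub = None if self.upper_bound is None else self.upper_bound * phi
        return WeightedGraph(
            self.names, {k: w * phi for k, w in self._edges.items()}, ub
        )

    # -- conversions ----------------------------------------------------

    def to_igraph(self):
        import igraph

        g = igraph.Graph(
            n=self.n,
            edges=list(self._edges.keys()),
            edge_attrs={"weight": list(self._edges.values())},
        )
        g.vs["name"] = self.names
        return g

    def induced_subgraph(self, vertices: Sequence[int]) -> "WeightedGraph":
        vset = {int(v): k for k, v in enumerate(vertices)}
        edges = {}
        for (i, j), w in self._edges.items():
            if i in vset and j in vset:
                edges[_edge_key(vset[i], vset[j])] = w
        return WeightedGraph(
            [self.names[v] for v in vertices], edges, self.upper_bound
        )

    # -- I/O --------------------------------------------------------------

    def write_edgelist(self, path) -> None:
        with open(path, "w") as fh:
            for (i, j), w in sorted(self._edges.items()):
                fh.write(f"{self.names[i]} {self.names[j]} {w!r}\n")


def read_graph(
    path,
    format: str = "edgelist",
    upper_bound: Optional[float] = None,
) -> WeightedGraph:
    """Read a graph from an edge-list or GraphML file.

    Edge lists are whitespace- or comma-separated ``u v [w]`` lines with
    ``#`` comments; a missing weight column means weight 1.  Duplicate
    edge lines are summed into one weighted edge.
    """
    if format == "edgelist":
        triples = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                parts = line.replace(",", " ").split()
                if len(parts) == 2:
                    u, v = parts
                    w = 1.0
                elif len(parts) == 3:
                    u, v = parts[:2]
                    try:
                        w = float(parts[2])
                    except ValueError as exc:
                        raise GraphError(
                            f"line {lineno}: bad weight {parts[2]!r}"
                        ) from exc
                else:
                    raise GraphError(f"line {lineno}: expected 'u v [w]'")
                triples.append((u, v, w))
        return WeightedGraph.from_edges(triples, upper_bound=upper_bound)
    if format == "graphml":
        import igraph

        ig = igraph.Graph.Read_GraphML(str(path))
        names = (
            [str(v) for v in ig.vs["name"]]
            if "name" in ig.vs.attributes()
            else [str(i) for i in range(ig.vcount())]
        )
        has_w = "weight" in ig.es.attributes()
        triples = [
            (names[e.source], names[e.target], e["weight"] if has_w else 1.0)
            for e in ig.es
        ]
        return WeightedGraph.from_edges(
            triples, upper_bound=upper_bound, names=names
        )
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Partitions
# ---------------------------------------------------------------------------


class VertexPartition:
    """Membership labelling of vertices into clusters.

    Stores a dense 0-based integer label per vertex (canonicalized by
    first appearance) together with the original labels for reporting.
    """

    def __init__(self, labels: Sequence, names: Optional[Sequence[str]] = None):
        raw = list(labels)
        if not raw:
            raise ValueError("empty partition")
        seen: Dict[object, int] = {}
        membership = np.empty(len(raw), dtype=int)
        for k, lab in enumerate(raw):
            if lab not in seen:
                seen[lab] = len(seen)
            membership[k] = seen[lab]
        self.membership: np.ndarray = membership
        self.original_labels: List[object] = list(seen)
        self.names = list(names) if names is not None else None
        if self.names is not None and len(self.names) != len(raw):
            raise ValueError("names/labels length mismatch")

    def __len__(self) -> int:
        return len(self.membership)

    def __eq__(self, other) -> bool:
        if not isinstance(other, VertexPartition):
            return NotImplemented
        return np.array_equal(self.membership, other.membership)

    @property
    def n_clusters(self) -> int:
        return len(self.original_labels)

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.membership, minlength=self.n_clusters)

    def clusters(self) -> List[np.ndarray]:
        return [
            np.flatnonzero(self.membership == c)
            for c in range(self.n_clusters)
        ]

    @property
    def is_degenerate(self) -> bool:
        """True for the two uninformative outputs: one cluster, or all
        singletons (on more than one vertex)."""
        n = len(self.membership)
        return self.n_clusters == 1 or (self.n_clusters == n and n > 1)


def read_membership(path, graph: Optional[WeightedGraph] = None) -> VertexPartition:
    """Read 'vertex label' pairs, one per line; '#' comments ignored.

    When ``graph`` is given the labels are reordered to the graph's vertex
    ids and checked for coverage.
    """
    pairs: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise ValueError("membership lines must be 'vertex label'")
            pairs[parts[0]] = parts[1]
    if graph is None:
        names = list(pairs)
        return VertexPartition([pairs[v] for v in names], names=names)
    labels = []
    for v in graph.names:
        if v not in pairs:
            raise ValueError(f"vertex {v!r} missing from membership file")
        labels.append(pairs[v])
    return VertexPartition(labels, names=graph.names)


def write_membership(path, p: VertexPartition, names: Optional[Sequence[str]] = None) -> None:
    names = names if names is not None else p.names
    if names is None:
        names = [str(i) for i in range(len(p))]
    with open(path, "w") as fh:
        for v, c in zip(names, p.membership):
            fh.write(f"{v} {c}\n")


# ---------------------------------------------------------------------------
# Cluster aggregates
# ---------------------------------------------------------------------------


@dataclass
class ClusterAggregates:
    """Per-cluster and per-vertex sums consumed by the scoring functions.

    All fields are indexable by canonical cluster id (arrays of length
    ``n_clusters``) or vertex id (length ``n``).  Computed in a single
    pass over the edge list, so building them is O(m).
    """

    n_vertices: int
    n_clusters: int
    total_weight: float          # m~ of the whole graph
    total_edges: int             # m
    cluster_sizes: np.ndarray    # n_S
    internal_edges: np.ndarray   # m_S
    internal_weight: np.ndarray  # m~_S
    boundary_edges: np.ndarray   # c_S
    boundary_weight: np.ndarray  # c~_S
    degree: np.ndarray           # d(u)
    strength: np.ndarray         # d~(u)
    degree_within: np.ndarray    # d_S(u) for u's own cluster S
    strength_within: np.ndarray  # d~_S(u) for u's own cluster S
    membership: np.ndarray = field(repr=False, default=None)

    @property
    def out_strength(self) -> np.ndarray:
        """Per-vertex weight leaving the vertex's own cluster."""
        return self.strength - self.strength_within


def cluster_aggregates(g: WeightedGraph, p: VertexPartition) -> ClusterAggregates:
    """Cross-tabulate a graph against a partition in one edge-list pass."""
    if len(p) != g.n:
        raise ValueError(
            f"partition covers {len(p)} vertices but the graph has {g.n}"
        )
    memb = p.membership
    R = p.n_clusters
    n = g.n
    internal_edges = np.zeros(R, dtype=int)
    internal_weight = np.zeros(R)
    boundary_edges = np.zeros(R, dtype=int)
    boundary_weight = np.zeros(R)
    degree = np.zeros(n, dtype=int)
    strength = np.zeros(n)
    degree_within = np.zeros(n, dtype=int)
    strength_within = np.zeros(n)
    for (i, j), w in g._edges.items():
        ci, cj = memb[i], memb[j]
        degree[i] += 1
        degree[j] += 1
        strength[i] += w
        strength[j] += w
        if ci == cj:
            internal_edges[ci] += 1
            internal_weight[ci] += w
            degree_within[i] += 1
            degree_within[j] += 1
            strength_within[i] += w
            strength_within[j] += w
        else:
            boundary_edges[ci] += 1
            boundary_edges[cj] += 1
            boundary_weight[ci] += w
            boundary_weight[cj] += w
    return ClusterAggregates(
        n_vertices=n,
        n_clusters=R,
        total_weight=g.total_weight,
        total_edges=g.m,
        cluster_sizes=p.sizes,
        internal_edges=internal_edges,
        internal_weight=internal_weight,
        boundary_edges=boundary_edges,
        boundary_weight=boundary_weight,
        degree=degree,
        strength=strength,
        degree_within=degree_within,
        strength_within=strength_within,
        membership=memb,
    )
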