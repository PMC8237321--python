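import math

import numpy as np
import pytest

from clustval import (
    SCORES,
    VertexPartition,
    WeightedGraph,
    barrat_local_coefficient,
    cluster_aggregates,
    modularity,
    score_cluster,
    score_partition,
    weighted_clustering_coefficient,
)
from clustval.fixtures import triangle, two_cliques

from conftest import random_partition, random_weighted_graph


def agg_for(g, labels):
    p = VertexPartition(labels, names=g.names)
    return p, cluster_aggregates(g, p)


class TestClusterScores:
    @pytest.mark.parametrize(
        "score,expected",
        [
            ("conductance", 0.5),       # 2 / (2*1 + 2)
            ("expansion", 1.0),         # 2 / 2
            ("cut_ratio", 1.0),         # 2 / (2 * 1)
            ("internal_density", 1.0),  # 1 / C(2,2)
            ("edges_inside", 1.0),
            ("average_degree", 1.0),
            ("max_odf", 0.5),
            ("avg_odf", 0.5),
        ],
    )
    def test_unit_triangle_pair_cluster(self, unit_triangle, score, expected):
        _, agg = agg_for(unit_triangle, [0, 0, 1])
        assert score_cluster(unit_triangle, agg, 0, score) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "score", ["conductance", "expansion", "normalized_cut", "max_odf", "avg_odf"]
    )
    def test_whole_graph_external_scores_vanish(self, score):
        g = random_weighted_graph(np.random.default_rng(0))
        _, agg = agg_for(g, [0] * g.n)
        assert score_cluster(g, agg, 0, score) == 0.0

    def test_singleton_internal_density_undefined(self, unit_triangle):
        _, agg = agg_for(unit_triangle, [0, 0, 1])
        assert math.isnan(score_cluster(unit_triangle, agg, 1, "internal_density"))

    def test_isolated_empty_cluster_conductance_undefined(self):
        g = WeightedGraph(["a", "b", "c"], {(0, 1): 1.0})
        _, agg = agg_for(g, [0, 0, 1])
        assert math.isnan(score_cluster(g, agg, 1, "conductance"))
        assert math.isnan(score_cluster(g, agg, 1, "normalized_cut"))

    def test_symmetric_cliques_share_conductance(self, cliques):
        g, truth = cliques
        agg = cluster_aggregates(g, truth)
        c0 = score_cluster(g, agg, 0, "conductance")
        c1 = score_cluster(g, agg, 1, "conductance")
        assert c0 == pytest.approx(c1)
        mean, n_nan = score_partition(g, truth, "conductance")
        assert mean == pytest.approx(c0)
        assert n_nan == 0


class TestScaleBehaviour:
    @pytest.mark.parametrize("seed", range(6))
    def test_invariant_and_linear_classes(self, seed):
        rng = np.random.default_rng(seed)
        g = random_weighted_graph(rng, n=14, p=0.45)
        p = random_partition(rng, g.n, 3)
        phi = float(10 ** rng.uniform(-1, 1))
        g2 = g.scaled(phi)
        for name, spec in SCORES.items():
            v1, _ = score_partition(g, p, name)
            v2, _ = score_partition(g2, p, name)
            if math.isnan(v1):
                assert math.isnan(v2)
            elif spec.scale_class == "invariant":
                assert v2 == pytest.approx(v1, rel=1e-9), name
            else:
                assert v2 == pytest.approx(phi * v1, rel=1e-9), name

    def test_binary_graph_matches_unweighted_formulas(self):
        rng = np.random.default_rng(7)
        g = random_weighted_graph(rng, n=12, binary=True)
        p = random_partition(rng, g.n, 3)
        agg = cluster_aggregates(g, p)
        for c in range(p.n_clusters):
            n_s = agg.cluster_sizes[c]
            if n_s == 0:
                continue
            # unweighted formulas written from edge counts
            assert score_cluster(g, agg, c, "edges_inside") == agg.internal_edges[c]
            assert score_cluster(g, agg, c, "expansion") == (
                pytest.approx(agg.boundary_edges[c] / n_s)
            )


class TestModularity:
    def test_single_cluster_is_zero(self):
        g = random_weighted_graph(np.random.default_rng(1))
        assert modularity(g, VertexPartition([0] * g.n)) == pytest.approx(0.0)

    def test_unit_triangle_split(self, unit_triangle):
        p = VertexPartition([0, 0, 1], names=unit_triangle.names)
        assert modularity(unit_triangle, p) == pytest.approx(-2.0 / 9.0)

    def test_invariant_under_uniform_scaling(self, unit_triangle):
        p = VertexPartition([0, 0, 1], names=unit_triangle.names)
        assert modularity(unit_triangle.scaled(7.0), p) == pytest.approx(
            modularity(unit_triangle, p)
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_igraph(self, seed):
        rng = np.random.default_rng(seed)
        g = random_weighted_graph(rng, n=16, p=0.35)
        p = random_partition(rng, g.n, 3)
        ig = g.to_igraph()
        expected = ig.modularity(list(p.membership), weights="weight")
        assert modularity(g, p) == pytest.approx(expected, rel=1e-12)


def brute_force_wcc(g, w_bar, grid=10_000):
    """Oracle: midpoint numeric integration of C_t over a fine grid."""
    ig = g.to_igraph()
    total = 0.0
    for k in range(grid):
        t = (k + 0.5) * w_bar / grid
        keep = [e.index for e in ig.es if e["weight"] >= t]
        sub = ig.subgraph_edges(keep, delete_vertices=False)
        ct = sub.transitivity_undirected(mode="zero")
        total += ct
    return total / grid


class TestClusteringCoefficient:
    def test_equal_weight_complete_graph_is_one(self):
        g = WeightedGraph.complete(5, weights=np.full(10, 0.7))
        assert weighted_clustering_coefficient(g) == pytest.approx(1.0)

    def test_weighted_triangle_integral(self, weighted_triangle):
        # C_t = 1 on (0, 1], 0 afterwards; w_bar = 3
        assert weighted_clustering_coefficient(weighted_triangle) == (
            pytest.approx(1.0 / 3.0)
        )

    def test_binary_graph_equals_classical_transitivity(self):
        rng = np.random.default_rng(11)
        g = random_weighted_graph(rng, n=14, binary=True)
        expected = g.to_igraph().transitivity_undirected(mode="zero")
        assert weighted_clustering_coefficient(g) == pytest.approx(expected)

    def test_no_triplets_gives_nan(self):
        g = WeightedGraph(["a", "b"], {(0, 1): 1.0})
        assert math.isnan(weighted_clustering_coefficient(g))

    @pytest.mark.parametrize("seed", range(3))
    def test_sweep_matches_numeric_integration(self, seed):
        rng = np.random.default_rng(seed)
        g = random_weighted_graph(rng, n=10, p=0.5)
        w_bar = g.max_weight
        oracle = brute_force_wcc(g, w_bar, grid=4000)
        assert weighted_clustering_coefficient(g) == pytest.approx(
            oracle, abs=2.0 * w_bar / 4000 + 1e-9
        )

    def test_scale_invariance(self):
        rng = np.random.default_rng(21)
        g = random_weighted_graph(rng, n=10, p=0.5)
        assert weighted_clustering_coefficient(g.scaled(3.7)) == pytest.approx(
            weighted_clustering_coefficient(g), rel=1e-12
        )


class TestBarrat:
    def test_complete_weighted_graph_is_one(self):
        rng = np.random.default_rng(5)
        g = WeightedGraph.complete(6, weights=rng.uniform(0.1, 1.0, 15))
        for i in range(g.n):
            assert barrat_local_coefficient(g, i) == pytest.approx(1.0)

    def test_unit_triangle_vertex(self, unit_triangle):
        assert barrat_local_coefficient(unit_triangle, 0) == pytest.approx(1.0)

    def test_star_center_is_zero(self):
        g = WeightedGraph.from_edges(
            [("c", "a", 1), ("c", "b", 2), ("c", "d", 3)]
        )
        assert barrat_local_coefficient(g, g.index["c"]) == 0.0

    def test_degree_below_two_undefined(self):
        g = WeightedGraph(["a", "b"], {(0, 1): 1.0})
        assert math.isnan(barrat_local_coefficient(g, 0))
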