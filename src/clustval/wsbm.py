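"""Weighted stochastic block model benchmark generator.

Graphs with a planted community structure are produced by a multigraph
variant of the stochastic block model: edges of unit weight are added
one at a time, each step picking an unordered vertex pair (u, v) with
probability E[b(u), b(v)] / n_steps, where E is the symmetric matrix of
expected edge weights between blocks.  Accumulated counts become the
edge weights, so the total weight of every sample equals n_steps exactly
while each individual weight is (dependently) binomial.

The built-in benchmark uses block sizes (40, 25, 25, 10) and an
expectation matrix whose diagonal scales with a strength parameter
lambda: near lambda = 1 the graph is almost uniform; large lambda plants
communities any reasonable algorithm recovers exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .graph_core import VertexPartition, WeightedGraph

__all__ = [
    "WSBMSpec",
    "benchmark_spec",
    "BENCHMARK_SIZES",
    "n_steps",
    "sample",
    "lambda_sweep",
]

BENCHMARK_SIZES: Tuple[int, ...] = (40, 25, 25, 10)


def _benchmark_matrix(lam: float) -> np.ndarray:
    e = np.array(
        [
            [0.03, 0.01, 0.01, 0.03],
            [0.01, 0.02, 0.05, 0.02],
            [0.01, 0.05, 0.02, 0.01],
            [0.03, 0.02, 0.01, 0.03],
        ]
    )
    np.fill_diagonal(e, np.diag(e) * lam)
    return e


@dataclass(frozen=True)
class WSBMSpec:
    """Block sizes plus the symmetric expected-weight matrix."""

    block_sizes: Tuple[int, ...]
    expectation: np.ndarray = field(repr=False)

    def __post_init__(self):
        e = np.asarray(self.expectation, dtype=float)
        k = len(self.block_sizes)
        if e.shape != (k, k):
            raise ValueError("expectation matrix shape does not match blocks")
        if not np.allclose(e, e.T):
            raise ValueError("expectation matrix must be symmetric")
        if (e < 0).any():
            raise ValueError("expectation matrix must be nonnegative")
        if any(s <= 0 for s in self.block_sizes):
            raise ValueError("block sizes must be positive")
        object.__setattr__(self, "expectation", e)
        object.__setattr__(self, "block_sizes", tuple(int(s) for s in self.block_sizes))

    @property
    def n(self) -> int:
        return sum(self.block_sizes)

    def block_of(self) -> np.ndarray:
        return np.repeat(
            np.arange(len(self.block_sizes)), self.block_sizes
        )


def benchmark_spec(lam: float) -> WSBMSpec:
    """The (40, 25, 25, 10) benchmark with diagonal strength ``lam``."""
    return WSBMSpec(BENCHMARK_SIZES, _benchmark_matrix(lam))


def expected_total(spec: WSBMSpec, include_self_pairs: bool = False) -> float:
    """Sum of expected weights over admissible vertex pairs.

    By default self-pairs are excluded: the sum runs over unordered
    distinct pairs, i.e. C(|C_i|, 2) diagonal pairs per block, which is
    the count under which the per-step pair probabilities sum to one.
    ``include_self_pairs`` reproduces the alternative (1/2) * Sum
    |C_i||C_j| E_ij count for compatibility.
    """
    sizes = np.asarray(spec.block_sizes, dtype=float)
    e = spec.expectation
    off = 0.0
    k = len(sizes)
    for i in range(k):
        for j in range(i + 1, k):
            off += sizes[i] * sizes[j] * e[i, j]
    if include_self_pairs:
        diag = float((sizes**2 * np.diag(e)).sum()) / 2.0
    else:
        diag = float((sizes * (sizes - 1) / 2.0 * np.diag(e)).sum())
    return off + diag


def n_steps(spec: WSBMSpec, include_self_pairs: bool = False) -> int:
    """Number of unit-edge draws; the expected total rounded half-up."""
    total = expected_total(spec, include_self_pairs=include_self_pairs)
    if total <= 0:
        raise ValueError("expectation matrix has zero total weight")
    return int(math.floor(total + 0.5))


def _pair_probabilities(spec: WSBMSpec):
    """Unordered distinct pairs and their (normalized) draw probabilities."""
    block = spec.block_of()
    n = spec.n
    iu, ju = np.triu_indices(n, k=1)
    raw = spec.expectation[block[iu], block[ju]]
    return iu, ju, raw / raw.sum()


def sample(
    spec: WSBMSpec,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[WeightedGraph, VertexPartition]:
    """Draw one weighted graph plus its planted membership.

    Performs ``n_steps(spec)`` independent categorical draws over the
    unordered vertex pairs; repeated draws of a pair accumulate weight.
    The returned graph's total weight equals ``n_steps(spec)`` exactly.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    steps = n_steps(spec)
    iu, ju, p = _pair_probabilities(spec)
    counts = rng.multinomial(steps, p)
    nz = np.flatnonzero(counts)
    names = [str(v) for v in range(spec.n)]
    edges = {
        (int(iu[k]), int(ju[k])): float(counts[k]) for k in nz
    }
    g = WeightedGraph(names, edges)
    truth = VertexPartition(spec.block_of(), names=names)
    return g, truth


def lambda_sweep(
    lambdas: Sequence[float],
    algorithms,
    n_reps: int = 20,
    seed: int = 0,
    sizes: Sequence[int] = BENCHMARK_SIZES,
    relative_modularity: bool = False,
    n_null: int = 20,
):
    """Recovery of the planted partition as a function of lambda.

    For each lambda and replicate: sample a benchmark graph, run each
    algorithm, and record VI and ARI against the planted membership
    (optionally also relative modularity against the switching null).
    ``algorithms`` maps name -> callable ``(graph, seed) -> partition``.
    Returns a tidy DataFrame with one row per (lambda, rep, algorithm).
    """
    import pandas as pd

    from .similarity import adjusted_rand_index_partitions, variation_of_information

    rows: List[dict] = []
    for lam in lambdas:
        spec = WSBMSpec(tuple(sizes), _benchmark_matrix(lam))
        for rep in range(n_reps):
            g, truth = sample(spec, seed=seed * 100003 + rep)
            for name, algo in algorithms.items():
                p = algo(g, seed * 100003 + rep)
                row = {
                    "lambda": lam,
                    "rep": rep,
                    "algorithm": name,
                    "n_clusters": p.n_clusters,
                    "vi": variation_of_information(truth, p),
                    "ari": adjusted_rand_index_partitions(truth, p),
                }
                if relative_modularity:
                    from .significance import evaluate_significance

                    rep_df = evaluate_significance(
                        g,
                        {name: algo},
                        scores=["modularity"],
                        n_null=n_null,
                        seed=seed * 100003 + rep,
                    )
                    row["relative_modularity"] = float(
                        rep_df["relative"].iloc[0]
                    )
                rows.append(row)
    return pd.DataFrame(rows)
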