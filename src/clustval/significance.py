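"""Cluster significance against the switching null model.

A clustering is significant when its scores stand out from the
distribution of scores the same algorithm obtains on degree-preserving
randomizations of the graph.  For every (algorithm, score) pair the
report carries the original value, the null-ensemble mean, the relative
score original/null_mean, and the percentile rank of the original value
in the null distribution — near 1 for higher-is-better scores and near
0 for lower-is-better ones when the clustering is significant.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .graph_core import WeightedGraph, cluster_aggregates
from .scoring import SCORES, score_partition
from .switching import SwitchConfig, choose_method, randomize

__all__ = ["percentile_rank", "evaluate_significance"]


def percentile_rank(x: float, null_scores: Sequence[float]) -> float:
    """Mid-rank percentile of ``x`` within ``null_scores``.

    (#{y < x} + 0.5 * #{y == x}) / N, so a value equal to the whole null
    sample sits at 0.5.
    """
    arr = np.asarray(null_scores, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return math.nan
    below = int((arr < x).sum())
    ties = int((arr == x).sum())
    return (below + 0.5 * ties) / arr.size


def evaluate_significance(
    g: WeightedGraph,
    algorithms: Dict[str, object],
    scores: Optional[Sequence[str]] = None,
    n_null: int = 100,
    cfg: Optional[SwitchConfig] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Score clusterings on ``g`` and on a switching-null ensemble.

    Parameters
    ----------
    algorithms
        name -> callable ``(graph, seed) -> VertexPartition``.
    scores
        Score names from :data:`clustval.scoring.SCORES`; all by default.
    n_null
        Ensemble size; 100 gives percentile resolution 0.01.
    cfg
        Switching configuration; by default T=100 with the transfer rule
        chosen by density (constant variance above density 0.5).

    Returns a DataFrame with one row per (algorithm, score).
    """
    if not algorithms:
        raise ValueError("at least one algorithm is required")
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    score_names = list(scores) if scores is not None else list(SCORES)
    for s in score_names:
        if s not in SCORES:
            raise KeyError(f"unknown score {s!r}")
    if cfg is None:
        cfg = SwitchConfig(method=choose_method(g), seed=seed)
    rng = np.random.default_rng(cfg.seed if cfg.seed is not None else seed)

    originals: Dict[str, dict] = {}
    for name, algo in algorithms.items():
        p = algo(g, int(rng.integers(2**31)))
        vals = {s: score_partition(g, p, s)[0] for s in score_names}
        originals[name] = {
            "partition": p,
            "values": vals,
            "degenerate": p.is_degenerate,
            "n_clusters": p.n_clusters,
        }

    null_values: Dict[str, Dict[str, List[float]]] = {
        name: {s: [] for s in score_names} for name in algorithms
    }
    for _ in range(n_null):
        g_null = randomize(g, replace(cfg, seed=int(rng.integers(2**31))))
        for name, algo in algorithms.items():
            p_null = algo(g_null, int(rng.integers(2**31)))
            for s in score_names:
                null_values[name][s].append(
                    score_partition(g_null, p_null, s)[0]
                )

    rows = []
    for name in algorithms:
        orig = originals[name]
        for s in score_names:
            nulls = np.asarray(null_values[name][s], dtype=float)
            defined = nulls[~np.isnan(nulls)]
            null_mean = float(defined.mean()) if defined.size else math.nan
            x = orig["values"][s]
            rows.append(
                {
                    "algorithm": name,
                    "score": s,
                    "direction": SCORES[s].direction,
                    "original": x,
                    "null_mean": null_mean,
                    "relative": (
                        x / null_mean
                        if null_mean not in (0.0,) and not math.isnan(null_mean)
                        else math.nan
                    ),
                    "percentile": percentile_rank(x, nulls),
                    "n_null": n_null,
                    "n_null_defined": int(defined.size),
                    "n_clusters_original": orig["n_clusters"],
                    "degenerate_partition": orig["degenerate"],
                }
            )
    return pd.DataFrame(rows)
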