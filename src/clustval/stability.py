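"""Cluster stability by nonparametric bootstrap with perturbation.

Vertices are resampled with replacement; the replicate graph carries the
edges the original graph induces on the resampled multiset.  Copies of
the same vertex are tied together by heavy edges (the weight upper bound
when the graph has one, otherwise values drawn from the top quantile of
the original weights), and every edge weight is jittered with truncated
normal noise so that weights stay within their bounds.  Each replicate
is re-clustered and compared — via VI, NRMI and ARI — with the original
partition pulled back through the resampling map (a copy inherits its
source vertex's original label).  Stable clusterings give VI near 0 and
NRMI/ARI near 1; a parallel run on a switching-randomized graph provides
the no-structure baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .graph_core import VertexPartition, WeightedGraph
from .similarity import (
    adjusted_rand_index_partitions,
    reduced_mutual_information,
    variation_of_information,
)
from .switching import SwitchConfig, choose_method, randomize

__all__ = ["BootConfig", "bootstrap_graph", "boot"]

UPPER_BOUND = "upper_bound"
TOP_QUANTILE = "top_quantile"


@dataclass(frozen=True)
class BootConfig:
    """Bootstrap parameters.

    ``noise_sd`` is the standard deviation of the truncated-normal
    weight jitter; None means 0.1 times the empirical standard
    deviation of the original edge weights.  ``duplicate_policy``
    controls the weight of edges tying copies of one vertex together.
    """

    R: int = 999
    noise_sd: Optional[float] = None
    duplicate_policy: str = "auto"
    top_quantile: float = 0.05
    seed: Optional[int] = None

    def __post_init__(self):
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.duplicate_policy not in ("auto", UPPER_BOUND, TOP_QUANTILE):
            raise ValueError(
                f"unknown duplicate policy {self.duplicate_policy!r}"
            )
        if not (0 < self.top_quantile <= 1):
            raise ValueError("top_quantile must be in (0, 1]")


def _resolve(cfg: BootConfig, g: WeightedGraph) -> Tuple[str, float]:
    policy = cfg.duplicate_policy
    if policy == "auto":
        policy = UPPER_BOUND if g.upper_bound is not None else TOP_QUANTILE
    if policy == UPPER_BOUND and g.upper_bound is None:
        raise ValueError(
            "duplicate_policy='upper_bound' requires a graph upper bound"
        )
    if cfg.noise_sd is not None:
        sd = cfg.noise_sd
    else:
        w = g.weights_array()
        sd = 0.1 * float(w.std(ddof=1)) if w.size > 1 else 0.0
    return policy, sd


def bootstrap_graph(
    g: WeightedGraph,
    cfg: BootConfig,
    rng: np.random.Generator,
    indices: Optional[Sequence[int]] = None,
) -> Tuple[WeightedGraph, np.ndarray]:
    """One bootstrap replicate: induced graph plus the index map.

    ``indices`` (mainly for testing) fixes the resampled vertex ids
    instead of drawing them; the returned index map sends each replicate
    vertex to its source vertex in ``g``.
    """
    n = g.n
    if indices is None:
        idx = np.sort(rng.integers(0, n, size=n))
    else:
        idx = np.asarray(list(indices), dtype=int)
    policy, sd = _resolve(cfg, g)
    names = [f"{g.names[v]}#{k}" for k, v in enumerate(idx)]
    edges: Dict[Tuple[int, int], float] = {}
    for i in range(len(idx)):
        for j in range(i + 1, len(idx)):
            w = g.weight(idx[i], idx[j])
            if w > 0:
                edges[(i, j)] = w
    # heavy clique among copies of the same vertex
    dup_pairs = [
        (i, j)
        for i in range(len(idx))
        for j in range(i + 1, len(idx))
        if idx[i] == idx[j]
    ]
    if dup_pairs:
        if policy == UPPER_BOUND:
            heavy = np.full(len(dup_pairs), g.upper_bound)
        else:
            w = np.sort(g.weights_array())
            k = max(1, int(math.ceil(cfg.top_quantile * w.size)))
            heavy = rng.choice(w[-k:], size=len(dup_pairs), replace=True)
        for (i, j), h in zip(dup_pairs, heavy):
            edges[(i, j)] = float(h)
    if sd > 0 and edges:
        keys = list(edges)
        w = np.array([edges[k] for k in keys])
        hi = g.upper_bound if g.upper_bound is not None else math.inf
        lo_std = (0.0 - w) / sd
        hi_std = (hi - w) / sd if hi != math.inf else np.full_like(w, math.inf)
        noise = stats.truncnorm.rvs(
            lo_std, hi_std, scale=sd, random_state=rng
        )
        for key, val in zip(keys, w + noise):
            edges[key] = float(val)
    g_rep = WeightedGraph(names, edges, upper_bound=g.upper_bound)
    return g_rep, idx


def boot(
    g: WeightedGraph,
    algorithms: Dict[str, object],
    cfg: Optional[BootConfig] = None,
    include_null_baseline: bool = False,
    switch_cfg: Optional[SwitchConfig] = None,
) -> pd.DataFrame:
    """Bootstrap stability of each algorithm's clustering of ``g``.

    Returns a tidy DataFrame with one row per (graph, algorithm,
    replicate) carrying vi / nrmi / ari of the replicate clustering
    against the pulled-back original, plus degeneracy flags.  With
    ``include_null_baseline`` the same procedure runs on a
    switching-randomized copy of ``g`` (graph = "randomized").
    """
    cfg = cfg or BootConfig()
    rng = np.random.default_rng(cfg.seed)
    targets = [("original", g)]
    if include_null_baseline:
        sw = switch_cfg or SwitchConfig(
            method=choose_method(g), seed=int(rng.integers(2**31))
        )
        targets.append(("randomized", randomize(g, sw)))

    rows = []
    for label, graph in targets:
        base: Dict[str, Optional[VertexPartition]] = {}
        for name, algo in algorithms.items():
            try:
                base[name] = algo(graph, int(rng.integers(2**31)))
            except Exception:  # noqa: BLE001 - replicate rows record it
                base[name] = None
        for rep in range(cfg.R):
            g_rep, idx = bootstrap_graph(graph, cfg, rng)
            for name, algo in algorithms.items():
                row = {
                    "graph": label,
                    "algorithm": name,
                    "replicate": rep,
                }
                try:
                    if base[name] is None:
                        raise RuntimeError(
                            f"{name} failed on the {label} graph"
                        )
                    p_rep = algo(g_rep, int(rng.integers(2**31)))
                except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                    row.update(
                        vi=math.nan, nrmi=math.nan, ari=math.nan,
                        failed=True, degenerate=False, error=str(exc),
                    )
                    rows.append(row)
                    continue
                pulled = VertexPartition(base[name].membership[idx])
                row.update(
                    vi=variation_of_information(pulled, p_rep),
                    nrmi=reduced_mutual_information(
                        pulled, p_rep, normalized=True, seed=rep
                    ),
                    ari=adjusted_rand_index_partitions(pulled, p_rep),
                    failed=False,
                    degenerate=p_rep.is_degenerate,
                    error="",
                )
                rows.append(row)
    return pd.DataFrame(rows)
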