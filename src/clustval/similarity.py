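"""Partition-comparison measures.

Information-theoretic measures (entropy, mutual information, variation
of information, reduced mutual information) and pair-counting measures
(Rand index, adjusted Rand index), all built on the contingency table of
two labelings of the same vertex set.  Natural logarithms throughout, so
entropies and mutual informations are in nats.

The reduced mutual information subtracts from I(r;s) the term
(1/n) log Omega(a, b), where Omega(a, b) counts the nonnegative integer
matrices with row sums a and column sums b.  This penalises the spurious
information carried by the margins themselves and repairs the classic
pathology of (N)MI, which assigns maximal similarity to any partition
compared with the all-singletons partition.  Omega is computed exactly
by memoized enumeration when feasible, by a second-order (Gaussian
local-CLT) analytic estimate for larger tables with few clusters, or by
a hybrid Monte-Carlo scheme when the margins contain many ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple, Union

import numpy as np

from .graph_core import VertexPartition

__all__ = [
    "ContingencyTable",
    "OmegaEstimate",
    "contingency",
    "entropy",
    "mutual_information",
    "variation_of_information",
    "rand_index",
    "adjusted_rand_index",
    "adjusted_rand_index_partitions",
    "count_tables",
    "reduced_mutual_information",
]

PartitionLike = Union[VertexPartition, Sequence[int], np.ndarray]


def _membership(p: PartitionLike) -> np.ndarray:
    if isinstance(p, VertexPartition):
        return p.membership
    return VertexPartition(list(p)).membership


@dataclass
class ContingencyTable:
    """Cross-tabulation of two partitions with margins."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or (c < 0).any():
            raise ValueError("counts must be a nonnegative 2-d matrix")
        self.counts = c

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def contingency(p1: PartitionLike, p2: PartitionLike) -> ContingencyTable:
    """Exact cross-tabulation of two partitions of the same vertex set."""
    m1, m2 = _membership(p1), _membership(p2)
    if len(m1) != len(m2):
        raise ValueError(
            f"partitions cover different vertex sets ({len(m1)} vs {len(m2)})"
        )
    r, s = m1.max() + 1, m2.max() + 1
    counts = np.zeros((r, s), dtype=np.int64)
    np.add.at(counts, (m1, m2), 1)
    return ContingencyTable(counts)


def entropy(p: PartitionLike) -> float:
    """Shannon entropy of the cluster-size distribution, in nats."""
    m = _membership(p)
    probs = np.bincount(m) / len(m)
    probs = probs[probs > 0]
    return float(-(probs * np.log(probs)).sum())


def mutual_information(t: ContingencyTable) -> float:
    """I(r;s) of the joint label distribution, in nats (0 log 0 := 0)."""
    n = t.n
    c = t.counts
    a = t.row_sums[:, None]
    b = t.col_sums[None, :]
    mask = c > 0
    p_rs = c[mask] / n
    indep = (a * b / (n * n))[mask]
    return float((p_rs * np.log(p_rs / indep)).sum())


def variation_of_information(p1: PartitionLike, p2: PartitionLike) -> float:
    """VI(r;s) = H(r) + H(s) - 2 I(r;s); a metric on partitions."""
    t = contingency(p1, p2)
    vi = entropy(p1) + entropy(p2) - 2.0 * mutual_information(t)
    return max(vi, 0.0)  # clip the tiny negative float residue at equality


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return x * (x - 1) / 2.0


def rand_index(t: ContingencyTable) -> float:
    """Fraction of vertex pairs on which the two partitions agree."""
    n = t.n
    total = n * (n - 1) / 2.0
    if total == 0:
        return 1.0
    same_both = _comb2(t.counts).sum()
    agreements = (
        total
        + 2.0 * same_both
        - (_comb2(t.row_sums).sum() + _comb2(t.col_sums).sum())
    )
    return float(agreements / total)


def adjusted_rand_index(t: ContingencyTable) -> float:
    """Rand index corrected for chance under the permutation model."""
    n = t.n
    total = n * (n - 1) / 2.0
    sum_c = _comb2(t.counts).sum()
    sum_a = _comb2(t.row_sums).sum()
    sum_b = _comb2(t.col_sums).sum()
    if total == 0:
        return 1.0
    expected = sum_a * sum_b / total
    maximum = 0.5 * (sum_a + sum_b)
    if maximum == expected:
        return 1.0  # both partitions trivial and identical
    return float((sum_c - expected) / (maximum - expected))


def adjusted_rand_index_partitions(p1: PartitionLike, p2: PartitionLike) -> float:
    return adjusted_rand_index(contingency(p1, p2))


# ---------------------------------------------------------------------------
# Counting contingency tables with fixed margins
# ---------------------------------------------------------------------------


@dataclass
class OmegaEstimate:
    """Natural log of the number of tables with given margins."""

    log_omega: float
    method: str
    mc_error: Optional[float] = None  # standard error of log_omega


class _ExactTooLarge(Exception):
    pass


def _omega_exact_count(
    a: Tuple[int, ...], b: Tuple[int, ...], max_states: int
) -> int:
    """Count tables by column-wise recursion with memoization.

    The state after filling a column is the multiset of remaining row
    sums, which collapses symmetric branches; ``max_states`` caps the
    memo size so infeasible inputs fail fast.
    """
    b_sorted = tuple(sorted(b, reverse=True))
    memo: Dict[Tuple[int, Tuple[int, ...]], int] = {}
    work = [0]

    def compositions(total: int, caps: Tuple[int, ...]):
        # all ways to split `total` over len(caps) cells with cell k <= caps[k]
        if not caps:
            if total == 0:
                yield ()
            return
        head = caps[0]
        tail = caps[1:]
        tail_max = sum(tail)
        lo = max(0, total - tail_max)
        hi = min(head, total)
        for x in range(lo, hi + 1):
            for rest in compositions(total - x, tail):
                yield (x,) + rest

    def rec(col: int, remaining: Tuple[int, ...]) -> int:
        if col == len(b_sorted):
            return 1  # remaining sums are all zero by conservation
        key = (col, remaining)
        hit = memo.get(key)
        if hit is not None:
            return hit
        total = 0
        for comp in compositions(b_sorted[col], remaining):
            work[0] += 1
            if work[0] > max_states:
                raise _ExactTooLarge
            nxt = tuple(
                sorted((r - x for r, x in zip(remaining, comp)), reverse=True)
            )
            total += rec(col + 1, nxt)
        memo[key] = total
        return total

    return rec(0, tuple(sorted(a, reverse=True)))


def _fit_max_entropy(a: np.ndarray, b: np.ndarray, tol: float = 1e-11):
    """Solve for x_r, y_s with sum_s z_rs = a_r, sum_r z_rs = b_s,
    where z_rs = x_r y_s / (1 - x_r y_s)."""
    n = a.sum()
    y = b / (n + b)  # keeps x*y < 1 at start
    x = np.ones_like(a, dtype=float)

    def solve(targets, other):
        # one bisection per margin, vectorised over the other side
        out = np.empty(len(targets))
        ymax = other.max()
        for i, t in enumerate(targets):
            lo, hi = 0.0, (1.0 - 1e-13) / ymax
            for _ in range(100):
                mid = 0.5 * (lo + hi)
                q = mid * other
                val = (q / (1.0 - q)).sum()
                if val < t:
                    lo = mid
                else:
                    hi = mid
            out[i] = 0.5 * (lo + hi)
        return out

    for _ in range(400):
        x = solve(a, y)
        y = solve(b, x)
        q = np.outer(x, y)
        z = q / (1.0 - q)
        err = max(
            np.abs(z.sum(axis=1) - a).max(), np.abs(z.sum(axis=0) - b).max()
        )
        if err < tol * max(1.0, n):
            break
    return x, y, z


def _omega_analytic(a_in: Sequence[int], b_in: Sequence[int]) -> float:
    """Analytic estimate of log Omega(a, b).

    Margins of value <= 3 carry too little mass for a central-limit
    treatment, so they are removed exactly: a column of sum v
    contributes a finite sum over the ways to distribute v among the
    rows.  The remaining core (all margins >= 4) is estimated by the
    Gaussian saddle point of :func:`_omega_analytic_core`; 2x2 cores
    use the closed form min(a1, b1) - max(0, a1 + b1 - n) + 1.
    """
    memo: Dict[Tuple[Tuple[int, ...], Tuple[int, ...]], float] = {}

    def rec(a: Tuple[int, ...], b: Tuple[int, ...], budget: int) -> float:
        a = tuple(sorted((v for v in a if v > 0)))
        b = tuple(sorted((v for v in b if v > 0)))
        if len(a) <= 1 or len(b) <= 1:
            return 1.0
        if len(b) < len(a) or (len(b) == len(a) and b[0] < a[0]):
            a, b = b, a
        if len(a) == 2 and len(b) == 2:
            n = a[0] + a[1]
            return float(min(a[0], b[0]) - max(0, a[0] + b[0] - n) + 1)
        key = (a, b)
        hit = memo.get(key)
        if hit is not None:
            return hit
        v = min(a[0], b[0])
        if v <= 3 and budget > 1:
            # peel the smallest margin exactly; wlog it is a column of b
            if b[0] <= a[0]:
                small, rest_b, rows = b[0], b[1:], a
                swap = False
            else:
                small, rest_b, rows = a[0], a[1:], b
                swap = True
            total = 0.0
            comps = list(_bounded_compositions(small, rows))
            sub_budget = max(1, budget // max(1, len(comps)))
            for comp in comps:
                new_rows = tuple(r - x for r, x in zip(rows, comp))
                if swap:
                    total += rec(rest_b, new_rows, sub_budget)
                else:
                    total += rec(new_rows, rest_b, sub_budget)
            memo[key] = total
            return total
        out = math.exp(_omega_analytic_core(a, b))
        memo[key] = out
        return out

    a = [int(v) for v in a_in if v > 0]
    b = [int(v) for v in b_in if v > 0]
    if sum(a) != sum(b):
        raise ValueError("margins must have equal totals")
    val = rec(tuple(a), tuple(b), 20_000)
    return math.log(val) if val > 0 else -math.inf


def _bounded_compositions(total: int, caps: Sequence[int]):
    """All splits of ``total`` over len(caps) cells with cell k <= caps[k]."""
    if len(caps) == 0:
        if total == 0:
            yield ()
        return
    tail = caps[1:]
    tail_max = sum(tail)
    for x in range(max(0, total - tail_max), min(caps[0], total) + 1):
        for rest in _bounded_compositions(total - x, tail):
            yield (x,) + rest


def _omega_analytic_core(a_in: Sequence[int], b_in: Sequence[int]) -> float:
    """Second-order saddle-point estimate of log Omega(a, b).

    Models table entries as independent geometric variables tilted so
    the expected margins match (the maximum-entropy saddle point), then
    evaluates the probability that the margins are hit exactly with a
    multivariate local central-limit expansion (Gaussian leading term
    plus the third/fourth-cumulant Edgeworth correction).  Accurate when
    the number of clusters is well below the number of elements.
    """
    a = np.asarray([v for v in a_in if v > 0], dtype=float)
    b = np.asarray([v for v in b_in if v > 0], dtype=float)
    if a.sum() != b.sum():
        raise ValueError("margins must have equal totals")
    if len(a) <= 1 or len(b) <= 1:
        return 0.0  # a single row or column forces the table
    r_dim, s_dim = len(a), len(b)
    x, y, z = _fit_max_entropy(a, b)
    q = np.outer(x, y)
    # log of the tilted generating function at the saddle
    log_f = -(np.log1p(-q)).sum() - (a * np.log(x)).sum() - (b * np.log(y)).sum()
    # local CLT for the margin vector (one coordinate is redundant)
    v = z * (1.0 + z)  # variance of each geometric entry
    rr = np.diag(v.sum(axis=1))
    ss = np.diag(v.sum(axis=0))
    m_cov = np.block([[rr, v], [v.T, ss]])
    m_red = m_cov[:-1, :-1]
    sign, logdet = np.linalg.slogdet(m_red)
    if sign <= 0:
        raise ArithmeticError("covariance matrix not positive definite")
    dim = r_dim + s_dim - 1
    log_omega = log_f - 0.5 * (dim * math.log(2 * math.pi) + logdet)

    # Edgeworth correction at the centre: 1 + (1/8) sum_e k4_e g_ee^2
    #   - (1/12) sum_ef k3_e k3_f g_ef^3 - (1/8) sum_ef k3_e k3_f g_ee g_ef g_ff
    # with g_ef the inverse-covariance quadratic form between the margin
    # indicator vectors of entries e and f.
    w = np.linalg.inv(m_red)
    k3 = z * (1.0 + z) * (1.0 + 2.0 * z)
    k4 = z * (1.0 + z) * (1.0 + 6.0 * z * (1.0 + z))
    # indicator of entry (r, s): coordinates r and r_dim + s (s < s_dim-1)
    n_e = r_dim * s_dim
    g = np.zeros((n_e, n_e))
    idx_r, idx_s = np.divmod(np.arange(n_e), s_dim)
    for e in range(n_e):
        re, se = idx_r[e], idx_s[e]
        for f in range(e, n_e):
            rf, sf = idx_r[f], idx_s[f]
            val = w[re, rf]
            if sf < s_dim - 1:
                val += w[re, r_dim + sf]
            if se < s_dim - 1:
                val += w[r_dim + se, rf]
                if sf < s_dim - 1:
                    val += w[r_dim + se, r_dim + sf]
            g[e, f] = g[f, e] = val
    k3_flat = k3.ravel()
    k4_flat = k4.ravel()
    g_diag = np.diag(g)
    term4 = 0.125 * float((k4_flat * g_diag**2).sum())
    term33_cross = (1.0 / 12.0) * float(k3_flat @ (g**3) @ k3_flat)
    k3g = k3_flat * g_diag
    term33_diag = 0.125 * float(k3g @ g @ k3g)
    corr = 1.0 + term4 - term33_cross - term33_diag
    if corr > 0.1:
        log_omega += math.log(corr)
    return float(log_omega)


def _omega_hybrid_mc(
    a_in: Sequence[int],
    b_in: Sequence[int],
    rng: np.random.Generator,
    n_samples: int,
) -> Tuple[float, float]:
    """Hybrid analytic + Monte-Carlo estimate for margins with many ones.

    The side with more unit margins is taken as rows.  Every table
    decomposes into a placement of the unit rows into columns plus a
    core table over the rows of margin > 1 with correspondingly reduced
    column margins, so

        Omega(a, b) = sum over placements v of Omega(core_a, b - v),

    which is S^k times an expectation over uniform placements.  That
    expectation is estimated by Monte Carlo, with the inner count from
    the analytic estimate (exact for tiny cores).  Returns
    (log_omega, standard error of log_omega).
    """
    a = np.asarray([v for v in a_in if v > 0], dtype=np.int64)
    b = np.asarray([v for v in b_in if v > 0], dtype=np.int64)
    if (a == 1).sum() < (b == 1).sum():
        a, b = b, a
    core = a[a > 1]
    k = int((a == 1).sum())
    s = len(b)
    if k == 0:
        return _omega_analytic(core, b), 0.0
    cache: Dict[Tuple[int, ...], float] = {}

    def inner(b_rem: np.ndarray) -> float:
        key = tuple(sorted(int(v) for v in b_rem if v > 0))
        val = cache.get(key)
        if val is None:
            if len(core) == 0:
                val = 1.0 if not key else 0.0
            elif len(key) <= 1:
                val = 1.0
            else:
                try:
                    val = math.exp(
                        _omega_exact_log(tuple(core), key, max_states=20000)
                    )
                except _ExactTooLarge:
                    val = math.exp(_omega_analytic(core, key))
        cache[key] = val
        return val

    draws = rng.integers(0, s, size=(n_samples, k))
    vals = np.empty(n_samples)
    for t in range(n_samples):
        counts = np.bincount(draws[t], minlength=s)
        b_rem = b - counts
        vals[t] = 0.0 if (b_rem < 0).any() else inner(b_rem)
    mean = vals.mean()
    if mean <= 0:
        raise ArithmeticError("Monte-Carlo estimate collapsed to zero")
    se = vals.std(ddof=1) / math.sqrt(n_samples)
    log_omega = k * math.log(s) + math.log(mean)
    return log_omega, se / mean


def _omega_exact_log(a, b, max_states: int) -> float:
    count = _omega_exact_count(tuple(a), tuple(b), max_states)
    return math.log(count) if count > 0 else -math.inf


def count_tables(
    a: Sequence[int],
    b: Sequence[int],
    method: str = "auto",
    seed: Optional[int] = None,
    n_samples: int = 10_000,
    max_states: int = 2_000_000,
) -> OmegaEstimate:
    """log Omega(a, b): the number of tables with the given margins.

    Methods: ``exact`` (memoized enumeration), ``analytic`` (Gaussian
    saddle-point estimate), ``mc`` (hybrid Monte-Carlo for margins with
    many ones), or ``auto`` which tries them in that order of
    preference.
    """
    a = [int(v) for v in a if v > 0]
    b = [int(v) for v in b if v > 0]
    if sum(a) != sum(b):
        raise ValueError("margins must have equal totals")
    if method == "exact":
        return OmegaEstimate(_omega_exact_log(a, b, max_states), "exact_enumeration")
    if method == "analytic":
        return OmegaEstimate(_omega_analytic(a, b), "analytic")
    if method == "mc":
        rng = np.random.default_rng(seed)
        log_om, err = _omega_hybrid_mc(a, b, rng, n_samples)
        return OmegaEstimate(log_om, "hybrid_mc", mc_error=err)
    if method != "auto":
        raise ValueError(f"unknown method {method!r}")
    if sum(a) <= 40 and len(a) * len(b) <= 20:
        try:
            # keep auto snappy: retreat to the estimates well before the
            # enumeration limit a caller may allow explicitly
            return OmegaEstimate(
                _omega_exact_log(a, b, min(max_states, 200_000)),
                "exact_enumeration",
            )
        except _ExactTooLarge:
            pass
    ones = max(sum(v == 1 for v in a), sum(v == 1 for v in b))
    if ones >= 5 and ones >= 0.25 * max(len(a), len(b)):
        rng = np.random.default_rng(seed)
        log_om, err = _omega_hybrid_mc(a, b, rng, n_samples)
        return OmegaEstimate(log_om, "hybrid_mc", mc_error=err)
    return OmegaEstimate(_omega_analytic(a, b), "analytic")


def reduced_mutual_information(
    p1: PartitionLike,
    p2: PartitionLike,
    normalized: bool = False,
    omega_method: str = "auto",
    seed: Optional[int] = None,
) -> float:
    """RMI(r;s) = I(r;s) - (1/n) log Omega(a, b); optionally normalized.

    The normalized form divides by the mean of RMI(r;r) and RMI(s;s).
    Returns NaN when that denominator is degenerate (both partitions a
    single cluster).
    """
    t = contingency(p1, p2)
    n = t.n
    a = t.row_sums
    b = t.col_sums
    i_rs = mutual_information(t)
    om_ab = count_tables(a, b, method=omega_method, seed=seed).log_omega
    rmi = i_rs - om_ab / n
    if not normalized:
        return float(rmi)
    om_aa = count_tables(a, a, method=omega_method, seed=seed).log_omega
    om_bb = count_tables(b, b, method=omega_method, seed=seed).log_omega
    denom = 0.5 * (entropy(p1) + entropy(p2) - (om_aa + om_bb) / n)
    if abs(denom) < 1e-15:
        return math.nan
    return float(rmi / denom)
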