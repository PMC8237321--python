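import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clustval import (
    VertexPartition,
    adjusted_rand_index,
    adjusted_rand_index_partitions,
    contingency,
    count_tables,
    entropy,
    mutual_information,
    rand_index,
    reduced_mutual_information,
    variation_of_information,
)
from clustval.similarity import _omega_analytic, _omega_exact_count

LOG2 = math.log(2.0)

memberships = st.lists(st.integers(0, 3), min_size=2, max_size=16)


def pair_count_oracle(m1, m2):
    """Oracle: type the C(n,2) vertex pairs directly (I/II/III/IV)."""
    n = len(m1)
    same_both = diff_both = 0
    for i, j in itertools.combinations(range(n), 2):
        s1 = m1[i] == m1[j]
        s2 = m2[i] == m2[j]
        same_both += s1 and s2
        diff_both += (not s1) and (not s2)
    total = n * (n - 1) // 2
    return same_both, diff_both, total


class TestContingency:
    def test_identical_partitions_give_diagonal(self):
        p = VertexPartition([0, 0, 1, 2])
        t = contingency(p, p)
        assert np.array_equal(np.diag(t.row_sums), t.counts)

    def test_hand_counted_table(self):
        t = contingency([0, 0, 1, 1], [0, 0, 0, 1])
        assert t.counts.tolist() == [[2, 0], [1, 1]]
        assert t.row_sums.tolist() == [2, 2]
        assert t.col_sums.tolist() == [3, 1]

    def test_singletons_vs_one_cluster(self):
        t = contingency([0, 1, 2, 3], [0, 0, 0, 0])
        assert t.counts.tolist() == [[1], [1], [1], [1]]

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValueError, match="different vertex sets"):
            contingency([0, 1], [0, 1, 2])


class TestInformationMeasures:
    def test_entropy_values(self):
        assert entropy([0, 0, 0]) == 0.0
        assert entropy([0, 1, 2, 3]) == pytest.approx(math.log(4))
        assert entropy([0, 0, 0, 1]) == pytest.approx(0.562335, abs=1e-6)

    def test_mutual_information_values(self):
        assert mutual_information(contingency([0, 0, 1, 1], [0, 1, 0, 1])) == (
            pytest.approx(0.0)
        )
        p = [0, 0, 1, 2]
        assert mutual_information(contingency(p, p)) == pytest.approx(entropy(p))
        assert mutual_information(contingency([0, 0, 1, 1], [0, 0, 0, 1])) == (
            pytest.approx(0.215761, abs=1e-6)
        )

    def test_vi_worked_example(self):
        assert variation_of_information([0, 0, 1, 1], [0, 0, 0, 1]) == (
            pytest.approx(0.823959, abs=1e-5)
        )

    @given(memberships)
    @settings(deadline=None)
    def test_vi_zero_iff_label_permutation(self, m):
        relabel = [(x * 7 + 3) % 11 for x in m]
        assert variation_of_information(m, relabel) == pytest.approx(0.0, abs=1e-12)

    @given(memberships, st.permutations(range(4)))
    @settings(deadline=None)
    def test_measures_invariant_under_relabeling(self, m, perm):
        m2 = [perm[x] for x in m]
        base = np.random.default_rng(0).integers(0, 3, len(m))
        for fn in (variation_of_information, adjusted_rand_index_partitions):
            assert fn(m, base) == pytest.approx(fn(m2, base), abs=1e-12)

    @given(memberships)
    @settings(deadline=None)
    def test_mi_bounded_by_entropies(self, m):
        rng = np.random.default_rng(1)
        other = rng.integers(0, 3, len(m))
        i = mutual_information(contingency(m, other))
        assert -1e-12 <= i <= min(entropy(m), entropy(other)) + 1e-12


class TestRandIndices:
    def test_identical_partitions(self):
        p = [0, 0, 1, 2, 2]
        assert rand_index(contingency(p, p)) == 1.0
        assert adjusted_rand_index(contingency(p, p)) == 1.0

    def test_worked_table(self):
        t = contingency([0, 0, 1, 1], [0, 0, 0, 1])
        assert rand_index(t) == pytest.approx(0.5)
        assert adjusted_rand_index(t) == pytest.approx(0.0)

    @given(memberships)
    @settings(deadline=None)
    def test_matches_pair_counting_and_sklearn(self, m):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(2)
        other = list(rng.integers(0, 3, len(m)))
        t = contingency(m, other)
        same, diff, total = pair_count_oracle(m, other)
        assert rand_index(t) == pytest.approx((same + diff) / total)
        assert adjusted_rand_index(t) == pytest.approx(
            adjusted_rand_score(m, other), abs=1e-12
        )


class TestCountTables:
    @pytest.mark.parametrize(
        "a,b,expected",
        [((2, 2), (3, 1), 2), ((1, 1, 1, 1), (2, 2), 6), ((1, 1, 1, 1), (1, 1, 1, 1), 24)],
    )
    def test_exact_small_values(self, a, b, expected):
        est = count_tables(a, b, method="exact")
        assert est.log_omega == pytest.approx(math.log(expected))

    def test_margin_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal totals"):
            count_tables((2, 2), (3, 2))

    @pytest.mark.parametrize("seed", range(8))
    def test_analytic_close_to_exact(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(15, 41))
        a = np.bincount(rng.integers(0, 3, n))
        b = np.bincount(rng.integers(0, 4, n))
        a = tuple(int(v) for v in a if v > 0)
        b = tuple(int(v) for v in b if v > 0)
        if len(a) < 2 or len(b) < 2:
            pytest.skip("degenerate margins")
        exact = math.log(_omega_exact_count(a, b, 10**7))
        assert _omega_analytic(a, b) == pytest.approx(exact, rel=0.02)

    def test_hybrid_mc_within_3_standard_errors(self):
        a = (1,) * 8 + (5, 4)
        b = (6, 5, 3, 2, 1)
        exact = math.log(
            _omega_exact_count(tuple(sorted(a, reverse=True)), b, 10**7)
        )
        est = count_tables(a, b, method="mc", seed=0, n_samples=20_000)
        assert est.method == "hybrid_mc"
        assert abs(est.log_omega - exact) <= 3 * est.mc_error + 1e-9

    def test_auto_prefers_exact_on_small_tables(self):
        assert count_tables((2, 2), (3, 1)).method == "exact_enumeration"


class TestReducedMutualInformation:
    def test_singletons_vs_halves_worked_value(self):
        # I = H = log 2; Omega((1,1,1,1),(2,2)) = 6
        rmi = reduced_mutual_information([0, 1, 2, 3], [0, 0, 1, 1])
        assert rmi == pytest.approx(LOG2 - math.log(6) / 4, abs=1e-9)
        assert rmi == pytest.approx(0.245207, abs=1e-6)

    def test_identical_partitions_normalize_to_one(self):
        p = [0, 0, 1, 1, 2]
        assert reduced_mutual_information(p, p, normalized=True) == (
            pytest.approx(1.0)
        )

    def test_singletons_vs_one_cluster_is_zero_not_maximal(self):
        # the pathology RMI fixes: NMI would score this as maximal
        nrmi = reduced_mutual_information(
            [0, 1, 2, 3], [0, 0, 0, 0], normalized=True
        )
        assert nrmi == pytest.approx(0.0, abs=1e-12)

    def test_both_trivial_partitions_flagged_nan(self):
        assert math.isnan(
            reduced_mutual_information([0, 0, 0], [0, 0, 0], normalized=True)
        )


class TestVIMetric:
    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(3)
        for _ in range(150):
            n = int(rng.integers(3, 31))
            ps = [rng.integers(0, rng.integers(1, 6) + 1, n) for _ in range(3)]
            d01 = variation_of_information(ps[0], ps[1])
            d12 = variation_of_information(ps[1], ps[2])
            d02 = variation_of_information(ps[0], ps[2])
            assert d02 <= d01 + d12 + 1e-9
            assert d01 == pytest.approx(
                variation_of_information(ps[1], ps[0]), abs=1e-12
            )
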