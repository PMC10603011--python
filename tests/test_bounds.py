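import math

import numpy as np
import pytest

from entrobound import (
    BoundQuery,
    InfeasibleQueryError,
    bounds,
    entropy_lower_bound,
    entropy_upper_bound,
    feasible_interval,
    ith_abundance,
    max_entropy_vector,
    min_entropy_vector,
    shannon_entropy,
    term_entropy,
)

LN = math.log


def feasible_grid(i, n, points=25):
    iv = feasible_interval(i, n)
    return np.linspace(iv.lo, iv.hi, points)


class TestFeasibleInterval:
    @pytest.mark.parametrize("i,n,lo,hi", [
        (2, 10, 0.0, 0.5),
        (1, 4, 0.25, 1.0),
        (5, 5, 0.0, 0.2),
        (1, 1, 1.0, 1.0),
    ])
    def test_examples(self, i, n, lo, hi):
        iv = feasible_interval(i, n)
        assert (iv.lo, iv.hi) == pytest.approx((lo, hi))

    @pytest.mark.parametrize("i,n", [(0, 3), (4, 3), (1, 0)])
    def test_invalid_rank(self, i, n):
        with pytest.raises(InfeasibleQueryError):
            feasible_interval(i, n)


class TestQueryValidation:
    def test_rejects_p1_below_mean(self):
        with pytest.raises(InfeasibleQueryError, match="feasible interval"):
            BoundQuery(i=1, p_i=0.05, n=10)

    def test_rejects_pi_above_reciprocal_rank(self):
        with pytest.raises(InfeasibleQueryError, match="feasible interval"):
            BoundQuery(i=3, p_i=0.4, n=5)

    def test_clamps_epsilon_violations_to_boundary(self):
        q = BoundQuery(i=2, p_i=0.5 + 1e-12, n=4)
        assert q.p_i == 0.5
        q = BoundQuery(i=1, p_i=0.25 - 1e-12, n=4)
        assert q.p_i == 0.25


class TestExtremalVectors:
    def test_max_vector_single_dominant_matches_community_b(self):
        v = max_entropy_vector(BoundQuery(i=1, p_i=0.85, n=10))
        assert np.allclose(v.values, [0.85] + [1 / 60] * 9, atol=1e-15)

    def test_max_vector_forced_by_sum(self):
        v = max_entropy_vector(BoundQuery(i=2, p_i=0.5, n=2))
        assert np.allclose(v.values, [0.5, 0.5])

    def test_max_vector_low_abundance_branch(self):
        v = max_entropy_vector(BoundQuery(i=3, p_i=0.1, n=4))
        assert np.allclose(v.values, [0.4, 0.4, 0.1, 0.1])

    def test_min_vector_packs_copies_of_p1(self):
        v = min_entropy_vector(BoundQuery(i=1, p_i=0.4, n=5))
        assert np.allclose(v.values, [0.4, 0.4, 0.2, 0.0, 0.0])

    def test_min_vector_forced_by_sum_and_ordering(self):
        v = min_entropy_vector(BoundQuery(i=2, p_i=0.5, n=6))
        assert np.allclose(v.values, [0.5, 0.5, 0, 0, 0, 0])

    def test_min_vector_uniform_point_padded_with_zeros(self):
        v = min_entropy_vector(BoundQuery(i=3, p_i=1 / 3, n=5))
        assert np.allclose(v.values, [1 / 3, 1 / 3, 1 / 3, 0, 0])

    def test_zero_abundance_limits(self):
        # p_i = 0 for i >= 2: limits of the extremal constructions
        vmin = min_entropy_vector(BoundQuery(i=4, p_i=0.0, n=6))
        assert np.allclose(vmin.values, [1, 0, 0, 0, 0, 0])
        vmax = max_entropy_vector(BoundQuery(i=4, p_i=0.0, n=6))
        assert np.allclose(vmax.values, [1 / 3] * 3 + [0] * 3)

    @pytest.mark.parametrize("n", [2, 3, 5, 8])
    def test_extremal_vectors_are_sorted_and_pin_rank_i(self, n):
        for i in range(1, n + 1):
            for p in feasible_grid(i, n):
                if i == 1 and p == 0:
                    continue
                q = BoundQuery(i=i, p_i=float(p), n=n)
                for v in (max_entropy_vector(q), min_entropy_vector(q)):
                    assert np.all(np.diff(v.values) <= 1e-12)
                    assert ith_abundance(v, i) == pytest.approx(q.p_i, abs=1e-12)


class TestClosedFormBounds:
    @pytest.mark.parametrize("q,expected", [
        ((1, 0.85, 10), 0.75229),
        ((2, 0.5, 2), LN(2)),
        ((1, 0.25, 4), LN(4)),
        ((1, 0.1, 10), LN(10)),
        ((3, 0.0, 5), LN(2)),
    ])
    def test_upper_bound_examples(self, q, expected):
        assert entropy_upper_bound(BoundQuery(*q)) == pytest.approx(
            expected, abs=5e-6)

    @pytest.mark.parametrize("q,expected", [
        ((2, 0.0, 7), 0.0),
        ((3, 1 / 3, 5), LN(3)),
        ((1, 0.4, 5), 2 * term_entropy(0.4) + term_entropy(0.2)),
        ((1, 1.0, 3), 0.0),
    ])
    def test_lower_bound_examples(self, q, expected):
        assert entropy_lower_bound(BoundQuery(*q)) == pytest.approx(
            expected, abs=1e-12)

    def test_bundle_degenerate_at_p1_equal_one(self):
        res = bounds(BoundQuery(i=1, p_i=1.0, n=3))
        assert res.h_min == res.h_max == 0.0
        assert np.allclose(res.argmax.values, [1, 0, 0])
        assert np.allclose(res.argmin.values, [1, 0, 0])

    def test_bundle_half_half(self):
        res = bounds(BoundQuery(i=2, p_i=0.5, n=2))
        assert res.h_min == pytest.approx(LN(2), abs=1e-12)
        assert res.h_max == pytest.approx(LN(2), abs=1e-12)

    def test_bundle_p1_half_n10(self):
        res = bounds(BoundQuery(i=1, p_i=0.5, n=10))
        assert res.h_min == pytest.approx(LN(2), abs=1e-12)
        expected_max = term_entropy(0.5) + 9 * term_entropy(1 / 18)
        assert res.h_max == pytest.approx(expected_max, abs=1e-12)

    def test_ceiling_snap_at_exact_reciprocal(self):
        # 1/0.2 in floats is 5.000000000000001; the snap keeps k = 5
        res = bounds(BoundQuery(i=1, p_i=0.2, n=5))
        assert res.k_copies == 4
        assert res.h_min == pytest.approx(LN(5), abs=1e-12)

    def test_branch_bookkeeping(self):
        assert bounds(BoundQuery(i=1, p_i=0.5, n=4)).branch == "i=1"
        assert bounds(BoundQuery(i=2, p_i=0.4, n=4)).branch == "p_i >= 1/n"
        assert bounds(BoundQuery(i=3, p_i=0.1, n=6)).branch == "p_i < 1/n"
        assert bounds(BoundQuery(i=2, p_i=0.4, n=4)).k_copies == 2
        assert bounds(BoundQuery(i=3, p_i=0.1, n=6)).k_copies == 4


class TestStructuralProperties:
    @pytest.mark.parametrize("n", range(2, 8))
    def test_attainment_on_grid(self, n):
        """The closed-form bounds equal the entropy of their extremal vectors."""
        for i in range(1, n + 1):
            for p in feasible_grid(i, n):
                if i == 1 and p == 0:
                    continue
                q = BoundQuery(i=i, p_i=float(p), n=n)
                res = bounds(q)
                assert res.h_min <= res.h_max + 1e-12
                assert shannon_entropy(res.argmax) == pytest.approx(
                    res.h_max, abs=1e-12)
                assert shannon_entropy(res.argmin) == pytest.approx(
                    res.h_min, abs=1e-12)

    @pytest.mark.parametrize("n", [3, 5, 10])
    def test_upper_bound_branches_agree_at_1_over_n(self, n):
        for i in range(2, n + 1):
            eps = 1e-11
            at = entropy_upper_bound(BoundQuery(i=i, p_i=1 / n, n=n))
            below = entropy_upper_bound(BoundQuery(i=i, p_i=1 / n - eps, n=n))
            above = entropy_upper_bound(BoundQuery(i=i, p_i=1 / n + eps, n=n))
            assert at == pytest.approx(LN(n), abs=1e-12)
            assert below == pytest.approx(at, abs=1e-8)
            assert above == pytest.approx(at, abs=1e-8)

    @pytest.mark.parametrize("n", range(2, 8))
    def test_bounds_coincide_at_reciprocal_rank(self, n):
        # at p_i = 1/i the vector is fully determined: both bounds are ln i
        for i in range(1, n + 1):
            q = BoundQuery(i=i, p_i=1 / i, n=n)
            assert entropy_lower_bound(q) == pytest.approx(LN(i), abs=1e-12)
            assert entropy_upper_bound(q) == pytest.approx(LN(i), abs=1e-12)

    def test_lower_bound_is_independent_of_n(self):
        for i, p in [(1, 0.37), (2, 0.21), (3, 0.05), (4, 0.2)]:
            values = {entropy_lower_bound(BoundQuery(i=i, p_i=p, n=n))
                      for n in range(max(i, math.ceil(1 / p)), 40)}
            assert max(values) - min(values) == pytest.approx(0.0, abs=1e-15)

    def test_monotonicity_for_most_abundant(self):
        grid = np.linspace(0.1, 1.0, 1000)
        upper = [entropy_upper_bound(BoundQuery(1, float(p), 10)) for p in grid]
        lower = [entropy_lower_bound(BoundQuery(1, float(p), 10)) for p in grid]
        assert np.all(np.diff(upper) <= 1e-12)
        assert np.all(np.diff(lower) <= 1e-12)

    @pytest.mark.parametrize("i,n", [(2, 6), (3, 7), (4, 9)])
    def test_monotonicity_for_subsequent_ranks(self, i, n):
        grid = np.linspace(0.0, 1 / i, 1000)
        lower = np.array([entropy_lower_bound(BoundQuery(i, float(p), n))
                          for p in grid])
        upper = np.array([entropy_upper_bound(BoundQuery(i, float(p), n))
                          for p in grid])
        assert np.all(np.diff(lower) >= -1e-12)
        split = 1.0 / n
        assert np.all(np.diff(upper[grid <= split]) >= -1e-12)
        assert np.all(np.diff(upper[grid >= split]) <= 1e-12)

    def test_sandwich_on_random_communities(self, random_vectors):
        for p in random_vectors:
            h = shannon_entropy(p)
            for i in (1, 2, 3):
                if i > p.n:
                    continue
                q = BoundQuery(i=i, p_i=ith_abundance(p, i), n=p.n)
                assert entropy_lower_bound(q) - 1e-9 <= h
                assert h <= entropy_upper_bound(q) + 1e-9
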