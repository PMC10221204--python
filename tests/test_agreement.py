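"""Passing-Bablok, cusum linearity, Bland-Altman, Lin's CCC, %diff rule."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from parpbridge.agreement import (
    bland_altman,
    cusum_linearity_test,
    isr_assess,
    lins_ccc,
    passing_bablok,
    percent_diff,
    percent_diff_rule,
)


def pb_oracle(x, y):
    """Exhaustive pairwise-slope enumeration with the shifted median."""
    slopes, K = [], 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[j] - x[i], y[j] - y[i]
            if dx == 0 and dy == 0:
                continue
            s = math.inf if (dx == 0 and dy > 0) else (
                -math.inf if dx == 0 else dy / dx
            )
            if s == -1:
                continue
            if s < -1:
                K += 1
            slopes.append(s)
    S = sorted(slopes)
    N = len(S)
    if N % 2 == 1:
        b = S[(N + 1) // 2 + K - 1]
    else:
        b = 0.5 * (S[N // 2 + K - 1] + S[N // 2 + K])
    a = float(np.median([yi - b * xi for xi, yi in zip(x, y)]))
    return b, a


class TestPassingBablok:
    def test_identity_data(self):
        r = passing_bablok([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert r.slope == pytest.approx(1.0)
        assert r.intercept == pytest.approx(0.0)

    def test_exact_affine_data(self):
        r = passing_bablok([1, 2, 3, 4, 5], [3, 5, 7, 9, 11])
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(1.0)

    def test_seeded_instance_matches_enumeration_oracle(self):
        rng = np.random.default_rng(101)
        x = rng.uniform(1, 50, 11)
        y = 0.9 * x + rng.normal(0, 2, 11)
        r = passing_bablok(x, y)
        b, a = pb_oracle(list(x), list(y))
        assert r.slope == pytest.approx(b, rel=1e-12)
        assert r.intercept == pytest.approx(a, rel=1e-12)

    def test_tied_x_values_match_oracle(self):
        """Pairs sharing an x contribute signed infinite slopes."""
        x = [1.0, 1.0, 2.0, 3.0, 3.0, 4.0, 5.0]
        y = [1.1, 0.9, 2.2, 2.9, 3.3, 4.1, 5.2]
        r = passing_bablok(x, y)
        b, a = pb_oracle(x, y)
        assert r.slope == pytest.approx(b, rel=1e-12)
        assert r.intercept == pytest.approx(a, rel=1e-12)

    @given(scale=st.floats(0.1, 10))
    def test_scale_equivariance_on_positive_slope_data(self, scale):
        # unit x spacing with small noise keeps every pairwise slope positive,
        # the condition under which the shifted median is exactly equivariant
        rng = np.random.default_rng(7)
        x = np.arange(1.0, 16.0)
        y = 1.3 * x + rng.normal(0, 0.3, 15)
        r1 = passing_bablok(x, y)
        r2 = passing_bablok(x, y * scale)
        assert r2.slope == pytest.approx(r1.slope * scale, rel=1e-9)

    def test_swapping_axes_inverts_slope(self):
        rng = np.random.default_rng(9)
        x = np.arange(1.0, 16.0)
        y = 2.0 * x + rng.normal(0, 0.3, 15)
        forward = passing_bablok(x, y)
        backward = passing_bablok(y, x)
        assert backward.slope == pytest.approx(1 / forward.slope, rel=1e-9)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(1, 100, 30)
        y = x + rng.normal(0, 5, 30)
        r = passing_bablok(x, y)
        assert r.slope_ci[0] <= r.slope <= r.slope_ci[1]
        assert r.intercept_ci[0] <= r.intercept <= r.intercept_ci[1]

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            passing_bablok([2, 2, 2], [1, 2, 3])


class TestCusumLinearity:
    def test_exact_affine_is_linear(self):
        r = passing_bablok([1, 2, 3, 4, 5, 6], [2, 4, 6, 8, 10, 12])
        assert r.cusum.statistic == 0.0
        assert r.cusum.band == "p>0.05"

    def test_strong_curvature_detected(self):
        x = np.arange(1, 41, dtype=float)
        y = x**2
        r = passing_bablok(x, y)
        assert r.cusum.band in ("p<=0.05", "p<=0.01")

    def test_mirroring_residuals_preserves_statistic(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(1, 10, 15)
        y = x + rng.normal(0, 1, 15)
        r = passing_bablok(x, y)
        c1 = cusum_linearity_test(x, y, r.slope, r.intercept)
        mirrored = 2 * (r.intercept + r.slope * x) - y
        c2 = cusum_linearity_test(x, mirrored, r.slope, r.intercept)
        assert c2.statistic == pytest.approx(c1.statistic, rel=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            cusum_linearity_test([1, 2, 3], [1, 2, 3], 1.0, 0.0)


class TestBlandAltman:
    def test_identical_series(self):
        r = bland_altman([1, 2, 3], [1, 2, 3])
        assert r.bias == 0.0
        assert r.sd == 0.0

    def test_hand_arithmetic(self):
        r = bland_altman([0, 0, 0], [-1, 0, 1])
        assert r.bias == pytest.approx(0.0)
        assert r.sd == pytest.approx(1.0)
        assert r.loa_low == pytest.approx(-1.96)
        assert r.loa_high == pytest.approx(1.96)

    def test_bias_ci_uses_t_distribution(self):
        rng = np.random.default_rng(4)
        x = rng.normal(100, 10, 20)
        y = x + rng.normal(2, 5, 20)
        r = bland_altman(x, y)
        d = y - x
        half = stats.t.ppf(0.975, 19) * d.std(ddof=1) / math.sqrt(20)
        assert r.bias_ci == pytest.approx((d.mean() - half, d.mean() + half))

    def test_insufficient_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1], [1])


class TestLinsCCC:
    def test_perfect_concordance(self):
        assert lins_ccc([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_hand_computed_moments(self):
        # s_x2 = s_y2 = s_xy = 2/3, mean gap 1 -> 2*(2/3)/(4/3+1) = 4/7
        assert lins_ccc([1, 2, 3], [2, 3, 4]) == pytest.approx(4 / 7)

    @given(seed=st.integers(0, 200))
    def test_bounded_by_pearson(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 20)
        y = 0.5 * x + rng.normal(0, 1, 20)
        ccc = lins_ccc(x, y)
        pearson = np.corrcoef(x, y)[0, 1]
        assert abs(ccc) <= abs(pearson) + 1e-12

    def test_equals_pearson_when_moments_match(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 500)
        y = np.array(x)[::-1]  # same mean and variance exactly
        assert lins_ccc(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1], rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ZeroDivisionError):
            lins_ccc([5, 5, 5], [5, 5, 5])


class TestPercentDiffRule:
    def test_identical_series_pass(self):
        res = percent_diff_rule([1, 2, 3], [1, 2, 3])
        assert res.values == (0.0, 0.0, 0.0)
        assert res.passed

    def test_pairwise_mean_denominator(self):
        res = percent_diff_rule([120.0], [100.0])
        assert res.values[0] == pytest.approx(20 / 110 * 100)
        assert res.frac_within == 1.0

    def test_exact_boundary_counts_within(self):
        # %diff exactly 20: ec/c = 11/9
        res = percent_diff_rule([110.0], [90.0])
        assert res.values[0] == pytest.approx(20.0)
        assert res.n_within == 1

    def test_exact_two_thirds_fraction_passes(self):
        # 4 of 6 within
        ec = [100, 100, 100, 100, 200, 200]
        c = [100, 100, 100, 100, 100, 100]
        res = percent_diff_rule(ec, c)
        assert res.n_within == 4
        assert res.passed
        res_fail = percent_diff_rule([100, 100, 100, 200, 200, 200], c)
        assert not res_fail.passed

    @given(seed=st.integers(0, 100))
    def test_antisymmetric_under_series_exchange(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(50, 150, 10)
        b = rng.uniform(50, 150, 10)
        assert np.allclose(percent_diff(a, b), -percent_diff(b, a))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            percent_diff_rule([1, 2], [1])


class TestISR:
    def test_identical_runs_pass(self):
        res = isr_assess([100, 200], [100, 200])
        assert res.values == (0.0, 0.0)
        assert res.passed

    def test_repeat_orientation(self):
        res = isr_assess([100.0], [114.0])
        assert res.values[0] == pytest.approx(14 / 107 * 100)

    def test_all_small_differences_pass(self):
        rng = np.random.default_rng(5)
        orig = rng.uniform(100, 5000, 20)
        rep = orig * rng.uniform(0.88, 1.12, 20)
        res = isr_assess(orig, rep)
        assert max(abs(v) for v in res.values) < 14
        assert res.passed
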