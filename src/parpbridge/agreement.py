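"""Method-agreement statistics for paired concentration measurements.

Implements the suite used to judge whether plasma concentrations estimated
from dried blood spots agree with directly measured plasma concentrations:

* Passing-Bablok regression — a nonparametric structural regression based on
  the shifted median of all pairwise slopes, robust to measurement error in
  both variables, with rank-based confidence intervals and the cusum
  linearity test from the original publication;
* Bland-Altman analysis — bias (mean difference), its t-based confidence
  interval, +/-1.96 SD limits of agreement, and a Spearman trend test of the
  differences against the pairwise means;
* Lin's concordance correlation coefficient;
* the regulatory percent-difference rule (at least 67% of samples within
  +/-20%), shared with incurred-sample reanalysis.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PassingBablok",
    "passing_bablok",
    "PBResult",
    "cusum_linearity_test",
    "CusumResult",
    "BAResult",
    "bland_altman",
    "lins_ccc",
    "spearman_trend",
    "percent_diff",
    "percent_diff_rule",
    "PercentDiffResult",
    "isr_assess",
]


def _pairwise_slopes(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    """All valid pairwise slopes plus the offset K (count of slopes < -1).

    Pairs with identical x and identical y (0/0) are omitted; pairs with
    identical x but different y contribute signed infinite slopes; slopes
    exactly equal to -1 are omitted, and K counts slopes below -1 — the
    shift that makes the median estimator invariant to swapping axes.
    """
    n = x.size
    slopes = []
    K = 0
    for i in range(n - 1):
        dx = x[i + 1 :] - x[i]
        dy = y[i + 1 :] - y[i]
        for dxi, dyi in zip(dx, dy):
            if dxi == 0:
                if dyi == 0:
                    continue  # 0/0: undefined, omitted
                s = math.inf if dyi > 0 else -math.inf
            else:
                s = dyi / dxi
            if s == -1.0:
                continue
            if s < -1.0:
                K += 1
            slopes.append(s)
    return np.sort(np.asarray(slopes, dtype=float)), K


class PassingBablok(BaseEstimator, RegressorMixin):
    """Passing-Bablok structural regression.

    The slope is the shifted median of all pairwise slopes
    (y_j - y_i)/(x_j - x_i), i < j, with offset K equal to the number of
    slopes below -1; the intercept is median(y_i - slope * x_i).  95%
    confidence bounds come from the rank-based normal approximation
    C = z * sqrt(n(n-1)(2n+5)/18) of the original method.

    Attributes
    ----------
    slope_, intercept_ : float
    slope_ci_, intercept_ci_ : (low, high)
    cusum_ : CusumResult
        Linearity test on the fitted line.
    n_ : int
    """

    def __init__(self, conf_level: float = 0.95):
        self.conf_level = conf_level

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size:
            raise ValueError("x and y must have equal length")
        if x.size < 3:
            raise ValueError("need at least 3 paired points")
        if np.unique(x).size < 2:
            raise ValueError("degenerate input: all x identical")
        self.n_ = int(x.size)

        S, K = _pairwise_slopes(x, y)
        N = S.size
        if N == 0:
            raise ValueError("no valid pairwise slopes")

        # shifted median (1-based index median + K)
        if N % 2 == 1:
            b = S[(N + 1) // 2 + K - 1]
        else:
            b = 0.5 * (S[N // 2 + K - 1] + S[N // 2 + K])
        self.slope_ = float(b)
        self.intercept_ = float(np.median(y - b * x))

        n = x.size
        z = stats.norm.ppf(0.5 + self.conf_level / 2)
        C = z * math.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
        M1 = int(round((N - C) / 2.0))
        M2 = N - M1 + 1
        lo_idx = max(M1 + K, 1)
        hi_idx = min(M2 + K, N)
        b_lo = float(S[lo_idx - 1])
        b_hi = float(S[hi_idx - 1])
        self.slope_ci_ = (b_lo, b_hi)
        self.intercept_ci_ = (
            float(np.median(y - b_hi * x)),
            float(np.median(y - b_lo * x)),
        )

        self.cusum_ = cusum_linearity_test(x, y, self.slope_, self.intercept_)
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        return self.intercept_ + self.slope_ * np.asarray(X, dtype=float)

    def result(self) -> "PBResult":
        check_is_fitted(self, "slope_")
        return PBResult(
            slope=self.slope_,
            slope_ci=self.slope_ci_,
            intercept=self.intercept_,
            intercept_ci=self.intercept_ci_,
            cusum=self.cusum_,
            n=self.n_,
        )


@dataclass(frozen=True)
class CusumResult:
    """Cusum linearity test outcome: max |cusum| against Kolmogorov bounds."""

    statistic: float
    critical_05: float
    critical_01: float
    band: str  # "p>0.05", "p<=0.05" or "p<=0.01"

    @property
    def linear(self) -> bool:
        return self.band == "p>0.05"


@dataclass(frozen=True)
class PBResult:
    slope: float
    slope_ci: tuple
    intercept: float
    intercept_ci: tuple
    cusum: CusumResult
    n: int


def passing_bablok(x, y, conf_level: float = 0.95) -> PBResult:
    """Fit a Passing-Bablok regression and return its summary."""
    return PassingBablok(conf_level=conf_level).fit(x, y).result()


def cusum_linearity_test(x, y, slope: float, intercept: float) -> CusumResult:
    """Cusum test for deviation from linearity around a fitted line.

    Points above the line score +sqrt(L/l) and points below score
    -sqrt(l/L) (l, L the counts above and below); scores are accumulated in
    increasing order of the projection of each point along the fitted line
    and the maximum |cusum| is compared with Kolmogorov-Smirnov bounds
    1.36*sqrt(L+l+1) (5%) and 1.63*sqrt(L+l+1) (1%).  Reported as a band,
    matching how the test is conventionally tabulated.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.size < 5:
        raise ValueError("need at least 5 points for the cusum linearity test")
    resid = y - (intercept + slope * x)
    l = int(np.sum(resid > 0))
    L = int(np.sum(resid < 0))
    if l == 0 or L == 0:
        # all points on one side (or exactly on the line): no evidence of
        # nonlinearity by this test
        return CusumResult(0.0, 1.36 * math.sqrt(l + L + 1), 1.63 * math.sqrt(l + L + 1), "p>0.05")
    scores = np.where(resid > 0, math.sqrt(L / l), np.where(resid < 0, -math.sqrt(l / L), 0.0))
    # accumulate in rank order of position along the fitted line; the fitted
    # coordinate is monotone in x, which keeps |cusum| invariant under
    # mirroring the residuals about the line
    order = np.argsort(x, kind="stable")
    cusum = np.cumsum(scores[order])
    stat = float(np.max(np.abs(cusum)))
    h05 = 1.36 * math.sqrt(l + L + 1)
    h01 = 1.63 * math.sqrt(l + L + 1)
    if stat > h01:
        band = "p<=0.01"
    elif stat > h05:
        band = "p<=0.05"
    else:
        band = "p>0.05"
    return CusumResult(stat, h05, h01, band)


@dataclass(frozen=True)
class BAResult:
    """Bland-Altman summary (differences y - x, in ng/mL)."""

    bias: float
    bias_ci: tuple
    sd: float
    loa_low: float
    loa_high: float
    spearman_r: float
    spearman_p: float
    n: int
    mean_concentration: float


def spearman_trend(d, m) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p.

    Exact permutation p for n <= 8 (feasible enumeration), t approximation
    with average ranks otherwise.
    """
    d = np.asarray(d, dtype=float)
    m = np.asarray(m, dtype=float)
    n = d.size
    if n < 3 or np.all(d == d[0]) or np.all(m == m[0]):
        return float("nan"), float("nan")
    rho = float(stats.spearmanr(d, m).statistic)
    if n <= 8:
        rd = stats.rankdata(d)
        rm = stats.rankdata(m)
        obs = abs(np.corrcoef(rd, rm)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(rm):
            r = abs(np.corrcoef(rd, np.asarray(perm))[0, 1])
            count += r >= obs - 1e-12
            total += 1
        return rho, count / total
    return rho, float(stats.spearmanr(d, m).pvalue)


def bland_altman(x, y, *, loa_multiplier: float = 1.96) -> BAResult:
    """Bland-Altman agreement analysis of y against x.

    Differences d = y - x; bias = mean(d) with a t-based 95% CI; limits of
    agreement bias +/- 1.96 * SD(d); Spearman correlation between d and the
    pairwise means (x + y)/2 flags concentration-dependent trends.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    tcrit = stats.t.ppf(0.975, n - 1)
    half = tcrit * sd / math.sqrt(n)
    means = (x + y) / 2.0
    rho, p = spearman_trend(d, means)
    return BAResult(
        bias=bias,
        bias_ci=(bias - half, bias + half),
        sd=sd,
        loa_low=bias - loa_multiplier * sd,
        loa_high=bias + loa_multiplier * sd,
        spearman_r=rho,
        spearman_p=p,
        n=n,
        mean_concentration=float(means.mean()),
    )


def lins_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient.

    2 * s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2) with population (1/n)
    moments; penalises both scatter and departure from the identity line.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.size != y.size or x.size < 2:
        raise ValueError("need equal-length inputs with n >= 2")
    sx2 = float(np.var(x))
    sy2 = float(np.var(y))
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    gap = float(x.mean() - y.mean())
    denom = sx2 + sy2 + gap**2
    if denom == 0:
        raise ZeroDivisionError("both variances and the mean gap are zero")
    return 2.0 * sxy / denom


def percent_diff(a, b) -> np.ndarray:
    """Percent difference of a vs b against their pairwise mean:
    (a - b) / mean(a, b) * 100."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch between the two series")
    return (a - b) / ((a + b) / 2.0) * 100.0


@dataclass(frozen=True)
class PercentDiffResult:
    values: tuple
    frac_within: float
    n_within: int
    n: int
    tol: float
    required_fraction: float
    passed: bool


def percent_diff_rule(
    ec,
    c,
    tol: float = 20.0,
    required_fraction: float = 2.0 / 3.0,
) -> PercentDiffResult:
    """Regulatory agreement rule on paired concentration series.

    Per-sample %diff = (ec - c) / mean(ec, c) * 100; the rule passes when
    the fraction of samples with |%diff| <= tol reaches required_fraction.
    Boundary cases count as within (exactly 20.0% is within tolerance; a
    fraction of exactly 2/3 passes).
    """
    pd_vals = percent_diff(ec, c)
    n = pd_vals.size
    if n == 0:
        raise ValueError("empty input")
    within = np.abs(pd_vals) <= tol + 1e-12
    k = int(within.sum())
    frac = k / n
    passed = frac >= required_fraction - 1e-12
    return PercentDiffResult(
        values=tuple(float(v) for v in pd_vals),
        frac_within=frac,
        n_within=k,
        n=n,
        tol=tol,
        required_fraction=required_fraction,
        passed=bool(passed),
    )


def isr_assess(
    original,
    repeat,
    tol: float = 20.0,
    required_fraction: float = 2.0 / 3.0,
) -> PercentDiffResult:
    """Incurred-sample reanalysis: %diff = (repeat - original)/mean * 100,
    judged by the same two-thirds-within-20% rule."""
    return percent_diff_rule(repeat, original, tol=tol, required_fraction=required_fraction)
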