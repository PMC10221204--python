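"""Weighted linear calibration and weighting-factor selection.

Instrument response (analyte/IS peak-area ratio) is modelled as a straight
line in nominal concentration, fitted by weighted least squares with one of
the three weights conventional in regulated bioanalysis: w = 1, 1/x or 1/x2.
LC-MS/MS calibration noise is typically proportional to concentration
(constant CV), which makes ordinary least squares over-weight the top of the
range; the weighting factor is selected formally by first testing for
heteroscedasticity (variance-ratio F-test on LLOQ vs ULOQ replicates) and
then comparing the candidate fits on AIC, weighted residual sum of squares,
the sum of absolute percent relative error of the back-calculated
concentrations, and the weighted correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CalibrationPoint",
    "WEIGHTINGS",
    "percent_re",
    "WeightedCalibration",
    "fit_weighted_line",
    "back_calculate",
    "heteroscedasticity_ftest",
    "WeightingSelector",
    "select_weighting",
    "WeightingSelection",
]

#: Candidate weighting factors, weakest to strongest.
WEIGHTINGS = ("1", "1/x", "1/x^2")


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibrator: nominal concentration (ng/mL) and measured response."""

    level_label: str
    nominal: float
    response: float

    def __post_init__(self) -> None:
        if self.nominal <= 0:
            raise ValueError(f"nominal must be > 0, got {self.nominal}")
        if self.response < 0:
            raise ValueError(f"response must be >= 0, got {self.response}")


def percent_re(found: float, nominal: float) -> float:
    """Signed percent relative error of a back-calculated concentration.

    %RE = (C_found - C_nom) / C_nom * 100
    """
    nominal_arr = np.asarray(nominal, dtype=float)
    if np.any(nominal_arr <= 0):
        raise ValueError("nominal must be > 0")
    return (np.asarray(found, dtype=float) - nominal_arr) / nominal_arr * 100.0


def _weight_values(weighting: str, x: np.ndarray) -> np.ndarray:
    if weighting == "1":
        return np.ones_like(x)
    if weighting == "1/x":
        return 1.0 / x
    if weighting == "1/x^2":
        return 1.0 / x**2
    raise ValueError(f"unknown weighting {weighting!r}; expected one of {WEIGHTINGS}")


class WeightedCalibration(BaseEstimator, RegressorMixin):
    """Weighted straight-line calibration model.

    Minimises sum_i w_i (y_i - a - b x_i)^2 with w_i in {1, 1/x_i, 1/x_i^2}.

    Parameters
    ----------
    weighting : {"1", "1/x", "1/x^2"}, default "1/x^2"
        Weighting factor applied to the squared residuals.

    Attributes
    ----------
    slope_ : float
        Response per ng/mL.
    intercept_ : float
        Response at zero concentration.
    ss_ : float
        Weighted residual sum of squares.
    r_ : float
        Weighted Pearson correlation between observed and fitted responses.
    aic_ : float
        n * ln(SS_w / n) + 2k with k = 2 fitted parameters.
    re_by_point_ : ndarray
        Percent relative error of each back-calculated concentration.
    sum_abs_re_ : float
        Sum of absolute %RE over all calibration points.
    """

    def __init__(self, weighting: str = "1/x^2"):
        self.weighting = weighting

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size:
            raise ValueError("X and y must have the same length")
        if x.size < 3:
            raise ValueError("need at least 3 calibration points")
        if np.any(x <= 0):
            raise ValueError("nominal concentrations must be > 0")
        if np.unique(x).size < 2:
            raise ValueError("degenerate design: all nominal concentrations identical")

        w = _weight_values(self.weighting, x)
        sw = np.sqrt(w)
        design = np.column_stack([sw, sw * x])
        coef, *_ = np.linalg.lstsq(design, sw * y, rcond=None)
        self.intercept_, self.slope_ = float(coef[0]), float(coef[1])

        fitted = self.intercept_ + self.slope_ * x
        resid = y - fitted
        self.ss_ = float(np.sum(w * resid**2))
        self.tss_ = float(np.sum(w * (y - np.sum(w * y) / w.sum()) ** 2))
        self.n_points_ = int(x.size)

        # weighted Pearson correlation of observed vs fitted responses
        wsum = w.sum()
        ybar = np.sum(w * y) / wsum
        fbar = np.sum(w * fitted) / wsum
        cov = np.sum(w * (y - ybar) * (fitted - fbar))
        vy = np.sum(w * (y - ybar) ** 2)
        vf = np.sum(w * (fitted - fbar) ** 2)
        self.r_ = float(cov / np.sqrt(vy * vf)) if vy > 0 and vf > 0 else 1.0

        n = x.size
        # SS may be exactly 0 on noise-free data; AIC -> -inf is the honest answer
        with np.errstate(divide="ignore"):
            self.aic_ = float(n * np.log(self.ss_ / n) + 2 * 2)

        if self.slope_ == 0:
            self.re_by_point_ = np.full(n, np.nan)
            self.sum_abs_re_ = float("nan")
        else:
            found = (y - self.intercept_) / self.slope_
            self.re_by_point_ = percent_re(found, x)
            self.sum_abs_re_ = float(np.sum(np.abs(self.re_by_point_)))
        return self

    def predict(self, X):
        """Forward map: expected response at concentration X."""
        check_is_fitted(self, "slope_")
        x = np.asarray(X, dtype=float)
        return self.intercept_ + self.slope_ * x

    def back_calculate(self, response):
        """Inverse map: concentration producing the given response.

        The result may lie outside [LLOQ, ULOQ]; flagging is the caller's job.
        """
        check_is_fitted(self, "slope_")
        if self.slope_ == 0:
            raise ZeroDivisionError("degenerate fit: zero slope")
        return (np.asarray(response, dtype=float) - self.intercept_) / self.slope_


def fit_weighted_line(
    points: "list[CalibrationPoint]", weighting: str = "1/x^2"
) -> WeightedCalibration:
    """Fit a :class:`WeightedCalibration` to a sequence of calibrators."""
    x = [p.nominal for p in points]
    y = [p.response for p in points]
    return WeightedCalibration(weighting=weighting).fit(x, y)


def back_calculate(fit: WeightedCalibration, response):
    """Back-calculate concentration(s) from response(s) through a fit."""
    return fit.back_calculate(response)


def heteroscedasticity_ftest(
    reps_low,
    reps_high,
    alpha: float = 0.01,
    *,
    two_sided: bool = False,
) -> tuple[float, float, bool]:
    """Variance-ratio F-test for heteroscedasticity across the range.

    Compares replicate response variances at the ULOQ against the LLOQ.

    Parameters
    ----------
    reps_low, reps_high : array-like
        Replicate responses at the LLOQ and ULOQ respectively.
    alpha : float
        Significance level.
    two_sided : bool
        If True, use the larger/smaller variance as the statistic and the
        upper alpha/2 quantile; default compares s2_high/s2_low against the
        upper alpha quantile (responses grow with concentration, so under
        proportional noise the ULOQ variance is the larger one).

    Returns
    -------
    (F, critical, significant)
    """
    lo = np.asarray(reps_low, dtype=float)
    hi = np.asarray(reps_high, dtype=float)
    if lo.size < 2 or hi.size < 2:
        raise ValueError("need >= 2 replicates on each side")
    s2_lo = float(np.var(lo, ddof=1))
    s2_hi = float(np.var(hi, ddof=1))
    if s2_lo == 0:
        raise ZeroDivisionError("zero variance at LLOQ: F ratio undefined")

    if two_sided:
        if s2_hi >= s2_lo:
            F = s2_hi / s2_lo
            dfn, dfd = hi.size - 1, lo.size - 1
        else:
            F = s2_lo / s2_hi
            dfn, dfd = lo.size - 1, hi.size - 1
        critical = float(stats.f.ppf(1 - alpha / 2, dfn, dfd))
    else:
        F = s2_hi / s2_lo
        dfn, dfd = hi.size - 1, lo.size - 1
        critical = float(stats.f.ppf(1 - alpha, dfn, dfd))
    return float(F), critical, bool(F > critical)


@dataclass
class WeightingSelection:
    """Outcome of the formal weighting-factor comparison."""

    chosen: str
    metrics_table: dict = field(default_factory=dict)
    ftest_significant: bool = False
    rationale: str = ""
    fits: dict = field(default_factory=dict)


#: strength order used to break exact ties toward the stronger weighting
_STRENGTH = {w: i for i, w in enumerate(WEIGHTINGS)}


class WeightingSelector(BaseEstimator):
    """Select the calibration weighting factor by the formal procedure.

    Fits all candidate weightings, then:

    * if the LLOQ-vs-ULOQ variance F-test is *not* significant the data are
      treated as homoscedastic and w = 1 is kept;
    * otherwise candidates are ranked by AIC, then weighted SS, then the sum
      of absolute %RE, then |1 - r|, with exact ties broken toward the
      stronger weighting.

    Attributes
    ----------
    chosen_ : str
    metrics_ : dict mapping weighting -> dict(ss, r, aic, sum_abs_re)
    ftest_significant_ : bool
    rationale_ : str
    fits_ : dict mapping weighting -> fitted WeightedCalibration
    """

    def __init__(self, alpha: float = 0.01, candidates=WEIGHTINGS):
        self.alpha = alpha
        self.candidates = candidates

    def fit(self, X, y, *, reps_low, reps_high):
        fits = {
            w: WeightedCalibration(weighting=w).fit(X, y) for w in self.candidates
        }
        self.fits_ = fits
        self.metrics_ = {
            w: {
                "ss": f.ss_,
                "r": f.r_,
                "aic": f.aic_,
                "sum_abs_re": f.sum_abs_re_,
            }
            for w, f in fits.items()
        }
        F, crit, sig = heteroscedasticity_ftest(reps_low, reps_high, self.alpha)
        self.ftest_significant_ = sig

        if not sig:
            self.chosen_ = "1"
            self.rationale_ = (
                f"F-test not significant (F={F:.3g} <= critical {crit:.3g} at "
                f"alpha={self.alpha}); calibration treated as homoscedastic, w=1"
            )
            return self

        def key(w: str):
            # snap floating-point dust to exact zeros so a perfect fit under
            # every weighting is recognised as a genuine tie
            m = self.metrics_[w]
            fit = fits[w]
            ss = 0.0 if fit.tss_ > 0 and m["ss"] < 1e-16 * fit.tss_ else m["ss"]
            n = fit.n_points_
            with np.errstate(divide="ignore"):
                aic = float(n * np.log(ss / n) + 4) if ss >= 0 else m["aic"]
            sum_re = 0.0 if m["sum_abs_re"] < 1e-9 else m["sum_abs_re"]
            r_gap = abs(1.0 - m["r"])
            return (aic, ss, sum_re, 0.0 if r_gap < 1e-12 else r_gap, -_STRENGTH[w])

        ranked = sorted(self.candidates, key=key)
        self.chosen_ = ranked[0]
        tie = len(ranked) > 1 and key(ranked[0])[:2] == key(ranked[1])[:2]
        self.rationale_ = (
            f"F-test significant (F={F:.3g} > critical {crit:.3g}); chose "
            f"w={self.chosen_} by AIC/SS/sum|%RE|/|1-r| priority"
            + ("; AIC and SS tied, broke toward stronger weighting" if tie else "")
        )
        return self

    def selection(self) -> WeightingSelection:
        check_is_fitted(self, "chosen_")
        return WeightingSelection(
            chosen=self.chosen_,
            metrics_table=self.metrics_,
            ftest_significant=self.ftest_significant_,
            rationale=self.rationale_,
            fits=self.fits_,
        )


def select_weighting(
    points: "list[CalibrationPoint]",
    reps_low,
    reps_high,
    alpha: float = 0.01,
) -> WeightingSelection:
    """Run the weighting-factor selection on a sequence of calibrators."""
    x = [p.nominal for p in points]
    y = [p.response for p in points]
    sel = WeightingSelector(alpha=alpha).fit(x, y, reps_low=reps_low, reps_high=reps_high)
    return sel.selection()
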