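"""DBS-to-plasma bridging: eligibility, conversion factor, agreement report.

A dried blood spot measures whole-blood concentration, while therapeutic
targets are defined on plasma.  The bridge is a single average conversion
factor CF = mean(C_DBS / C_pla) per drug; an estimated plasma concentration
is then EC_pla = C_DBS / CF.  Clinical validation filters paired samples to
the hematocrit range the DBS assay was validated for (29-45%) and to recent
hematocrit determinations, then runs the full agreement suite between
EC_pla and the measured C_pla.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .agreement import (
    BAResult,
    PBResult,
    PercentDiffResult,
    bland_altman,
    lins_ccc,
    passing_bablok,
    percent_diff_rule,
)

__all__ = [
    "PairedSample",
    "HCT_RANGE",
    "MAX_DAYS_SINCE_HCT",
    "filter_eligible",
    "ConversionModel",
    "DbsToPlasmaConverter",
    "conversion_factor",
    "estimate_plasma",
    "AgreementReport",
    "agreement_report",
]

#: hematocrit range (percent, closed interval) the DBS assay is validated for
HCT_RANGE = (29.0, 45.0)
#: hematocrit determinations older than this are not considered current
MAX_DAYS_SINCE_HCT = 14.0

#: minimum data set recommended for establishing a conversion factor
MIN_SAMPLES = 40
MIN_SUBJECTS = 25


@dataclass(frozen=True)
class PairedSample:
    """One patient's time-matched plasma and DBS concentrations."""

    subject_id: str
    analyte: str
    c_pla: float
    c_dbs: float
    hct: float = float("nan")
    days_since_hct: float = float("nan")
    hours_since_dose: float = float("nan")

    def __post_init__(self) -> None:
        if self.c_pla <= 0 or self.c_dbs <= 0:
            raise ValueError("concentrations must be > 0")
        if not math.isnan(self.hct) and not (0 < self.hct < 100):
            raise ValueError("hct must be inside (0, 100)")

    @property
    def ratio(self) -> float:
        """Per-sample DBS-to-plasma concentration ratio."""
        return self.c_dbs / self.c_pla


def filter_eligible(
    samples,
    hct_range: tuple = HCT_RANGE,
    max_days_since_hct: float = MAX_DAYS_SINCE_HCT,
) -> tuple[list, list]:
    """Retain samples inside the validated Hct window with a current Hct.

    Returns the eligible subset and an exclusion log of
    ``(sample, reason)`` tuples.  Samples with an unknown (NaN) Hct are
    excluded; an unknown days-since-Hct is retained (no evidence against).
    """
    lo, hi = hct_range
    eligible: list = []
    log: list = []
    for s in samples:
        if math.isnan(s.hct):
            log.append((s, "hct-missing"))
        elif not (lo <= s.hct <= hi):
            log.append((s, "hct-out-of-range"))
        elif (not math.isnan(s.days_since_hct)) and s.days_since_hct > max_days_since_hct:
            log.append((s, "hct-determination-stale"))
        else:
            eligible.append(s)
    return eligible, log


@dataclass(frozen=True)
class ConversionModel:
    """Average DBS-to-plasma conversion factor for one analyte."""

    analyte: str
    cf: float
    n_samples: int
    n_subjects: int

    def __post_init__(self) -> None:
        if self.cf <= 0:
            raise ValueError("cf must be > 0")

    @property
    def meets_sample_size(self) -> bool:
        return self.n_samples >= MIN_SAMPLES and self.n_subjects >= MIN_SUBJECTS


class DbsToPlasmaConverter(BaseEstimator):
    """Estimate plasma concentration from a DBS measurement via a CF.

    Parameters
    ----------
    method : {"mean", "geometric", "regression"}, default "mean"
        How the CF is pooled across samples: arithmetic mean of per-sample
        C_DBS/C_pla ratios (default), geometric mean of the ratios, or the
        least-squares regression of C_DBS on C_pla through the origin.

    Attributes
    ----------
    cf_ : float
    n_samples_, n_subjects_ : int
    meets_sample_size_ : bool
        Whether the >= 40 samples / >= 25 subjects recommendation holds.
    """

    def __init__(self, method: str = "mean"):
        self.method = method

    def fit(self, samples):
        samples = list(samples)
        if not samples:
            raise ValueError("need at least one paired sample")
        analytes = {s.analyte for s in samples}
        if len(analytes) > 1:
            raise ValueError(f"mixed analytes in one CF fit: {sorted(analytes)}")
        ratios = np.array([s.ratio for s in samples], dtype=float)
        if self.method == "mean":
            cf = float(ratios.mean())
        elif self.method == "geometric":
            cf = float(np.exp(np.log(ratios).mean()))
        elif self.method == "regression":
            c_pla = np.array([s.c_pla for s in samples])
            c_dbs = np.array([s.c_dbs for s in samples])
            cf = float(np.sum(c_pla * c_dbs) / np.sum(c_pla**2))
        else:
            raise ValueError(f"unknown method {self.method!r}")
        self.analyte_ = analytes.pop()
        self.cf_ = cf
        self.n_samples_ = len(samples)
        self.n_subjects_ = len({s.subject_id for s in samples})
        self.meets_sample_size_ = (
            self.n_samples_ >= MIN_SAMPLES and self.n_subjects_ >= MIN_SUBJECTS
        )
        return self

    def predict(self, c_dbs):
        """EC_pla = C_DBS / CF."""
        check_is_fitted(self, "cf_")
        return np.asarray(c_dbs, dtype=float) / self.cf_

    def model(self) -> ConversionModel:
        check_is_fitted(self, "cf_")
        return ConversionModel(
            analyte=self.analyte_,
            cf=self.cf_,
            n_samples=self.n_samples_,
            n_subjects=self.n_subjects_,
        )


def conversion_factor(samples, method: str = "mean") -> ConversionModel:
    """Average conversion factor CF = mean(C_DBS / C_pla) for one analyte."""
    return DbsToPlasmaConverter(method=method).fit(samples).model()


def estimate_plasma(c_dbs, model: ConversionModel):
    """Estimated plasma concentration EC_pla = C_DBS / CF."""
    if model.cf <= 0:
        raise ValueError("invalid model: cf must be > 0")
    return np.asarray(c_dbs, dtype=float) / model.cf


@dataclass
class AgreementReport:
    """Full agreement analysis between EC_pla and C_pla for one analyte."""

    conversion: ConversionModel
    pb: PBResult
    ba: BAResult
    lins_ccc: float
    pct_diff: PercentDiffResult
    c_pla: tuple = field(default=(), repr=False)
    ec_pla: tuple = field(default=(), repr=False)

    @property
    def ema_fda_pass(self) -> bool:
        return self.pct_diff.passed


def agreement_report(samples, method: str = "mean") -> AgreementReport:
    """Fit the CF on the eligible samples of one analyte and run the full
    agreement suite of EC_pla against C_pla."""
    samples = list(samples)
    converter = DbsToPlasmaConverter(method=method).fit(samples)
    c_pla = np.array([s.c_pla for s in samples], dtype=float)
    c_dbs = np.array([s.c_dbs for s in samples], dtype=float)
    ec_pla = converter.predict(c_dbs)
    return AgreementReport(
        conversion=converter.model(),
        pb=passing_bablok(c_pla, ec_pla),
        ba=bland_altman(c_pla, ec_pla),
        lins_ccc=lins_ccc(c_pla, ec_pla),
        pct_diff=percent_diff_rule(ec_pla, c_pla),
        c_pla=tuple(c_pla),
        ec_pla=tuple(float(v) for v in ec_pla),
    )
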