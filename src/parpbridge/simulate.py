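"""Seeded generators emulating the study's data-generating assumptions.

Every pipeline stage is testable without external data:

* calibration runs — the eight-level ladder per analyte with either
  additive (constant-SD) or proportional (constant-CV) response noise; the
  proportional model is what real LC-MS/MS calibration noise looks like and
  is what makes 1/x2 weighting win the formal selection;
* QC replicate panels with a controllable bias and CV;
* paired plasma/DBS clinical samples — plasma trough concentrations are
  lognormal (positive, right-skewed), moment-matched per drug to the
  published mean +/- SD trough exposures; the DBS concentration is the
  plasma concentration times a fixed true blood-to-plasma ratio with
  multiplicative noise; hematocrit is uniform over the validated 29-45%
  window;
* incurred-sample reanalysis pairs with multiplicative run-to-run noise.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .analytes import ANALYTE_RANGES, AnalyteRange, LEVEL_LABELS
from .bridging import PairedSample
from .calibration import CalibrationPoint
from .validation import QCReplicateSet

__all__ = [
    "CalibSimConfig",
    "ClinicalSimConfig",
    "gen_calibration_run",
    "gen_qc_panel",
    "gen_paired_clinical",
    "gen_isr_pairs",
    "clinical_config_for",
    "STUDY_DESIGNS",
]


@dataclass(frozen=True)
class CalibSimConfig:
    """Configuration for one synthetic calibration run."""

    analyte: str = "niraparib"
    slope: float = 0.002  # response per ng/mL
    intercept: float = 0.0
    noise_model: str = "proportional"  # or "additive"
    noise_param: float = 5.0  # CV% (proportional) or SD in response units
    replicates_per_level: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_param < 0:
            raise ValueError("noise_param must be >= 0")
        if self.replicates_per_level < 1:
            raise ValueError("replicates_per_level must be >= 1")
        if self.noise_model not in ("proportional", "additive"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.analyte not in ANALYTE_RANGES:
            raise ValueError(f"unknown analyte {self.analyte!r}")


def gen_calibration_run(cfg: CalibSimConfig) -> list[CalibrationPoint]:
    """Synthesize an eight-level calibration run (replicated calibrators).

    Responses follow intercept + slope * x, perturbed multiplicatively
    (constant CV) or additively (constant SD).
    """
    rng = np.random.default_rng(cfg.seed)
    rng_range: AnalyteRange = ANALYTE_RANGES[cfg.analyte]
    nominals = rng_range.calibrator_nominals
    points: list[CalibrationPoint] = []
    for label, x in zip(reversed(LEVEL_LABELS), nominals):
        clean = cfg.intercept + cfg.slope * x
        for _ in range(cfg.replicates_per_level):
            if cfg.noise_model == "proportional":
                resp = clean * (1.0 + rng.normal(0.0, cfg.noise_param / 100.0))
            else:
                resp = clean + rng.normal(0.0, cfg.noise_param)
            points.append(CalibrationPoint(label, float(x), max(float(resp), 0.0)))
    return points


def gen_qc_panel(
    nominal: float,
    bias: float,
    cv: float,
    n: int,
    seed: int,
    *,
    analyte: str = "niraparib",
    condition: str = "within-run",
    is_lloq: bool = False,
) -> QCReplicateSet:
    """Replicate QC measurements: nominal * (1 + bias/100) * (1 + N(0, cv/100))."""
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    measured = nominal * (1.0 + bias / 100.0) * (1.0 + rng.normal(0.0, cv / 100.0, n))
    return QCReplicateSet(
        analyte=analyte,
        nominal=nominal,
        measured=tuple(float(m) for m in measured),
        condition=condition,
        is_lloq=is_lloq,
    )


def gen_calibration_study(
    cfg: CalibSimConfig, n_runs: int = 3
) -> list[CalibrationPoint]:
    """Pool several independent calibration runs of the same design.

    Heteroscedasticity and weighting selection are judged on replicate data
    across runs (a single run of duplicate calibrators leaves the variance
    F-test with one degree of freedom per side); run r uses seed
    ``cfg.seed * n_runs + r``.
    """
    points: list[CalibrationPoint] = []
    for r in range(n_runs):
        run_cfg = CalibSimConfig(
            analyte=cfg.analyte,
            slope=cfg.slope,
            intercept=cfg.intercept,
            noise_model=cfg.noise_model,
            noise_param=cfg.noise_param,
            replicates_per_level=cfg.replicates_per_level,
            seed=cfg.seed * n_runs + r,
        )
        points.extend(gen_calibration_run(run_cfg))
    return points


#: published trough exposure (mean, SD) in ng/mL used for plasma simulation
_TROUGH = {
    "niraparib": (649.0, 135.0),
    "rucaparib": (1754.0, 805.0),
    "olaparib": (1290.0, 0.76 * 1290.0),  # reported as mean with 76% CV
}

#: clinical-study design per analyte: (n_subjects, n_samples) and the
#: observed average blood-to-plasma conversion factor
STUDY_DESIGNS = {
    "olaparib": {"n_subjects": 16, "n_samples": 52, "cf_true": 0.718},
    "niraparib": {"n_subjects": 21, "n_samples": 43, "cf_true": 1.440},
    "rucaparib": {"n_subjects": 4, "n_samples": 16, "cf_true": 1.427},
}


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a lognormal to a given arithmetic mean and SD."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


@dataclass(frozen=True)
class ClinicalSimConfig:
    """Configuration for synthetic paired plasma/DBS clinical samples."""

    analyte: str = "niraparib"
    n_subjects: int = 21
    n_samples: int = 43
    cf_true: float = 1.440
    plasma_logmean: float = field(default=float("nan"))
    plasma_logsd: float = field(default=float("nan"))
    ratio_cv: float = 8.0  # percent multiplicative noise on the DBS/plasma ratio
    hct_low: float = 29.0
    hct_high: float = 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cf_true <= 0:
            raise ValueError("cf_true must be > 0")
        if not (0 < self.hct_low <= self.hct_high < 100):
            raise ValueError("hct bounds must satisfy 0 < low <= high < 100")
        if math.isnan(self.plasma_logmean) or math.isnan(self.plasma_logsd):
            mean, sd = _TROUGH.get(self.analyte, (1000.0, 400.0))
            mu, sig = _lognormal_params(mean, sd)
            object.__setattr__(self, "plasma_logmean", mu)
            object.__setattr__(self, "plasma_logsd", sig)


def clinical_config_for(analyte: str, seed: int = 0, **overrides) -> ClinicalSimConfig:
    """Study-design defaults (sample counts, CF) for one analyte."""
    design = STUDY_DESIGNS[analyte]
    kwargs = dict(
        analyte=analyte,
        n_subjects=design["n_subjects"],
        n_samples=design["n_samples"],
        cf_true=design["cf_true"],
        seed=seed,
    )
    kwargs.update(overrides)
    return ClinicalSimConfig(**kwargs)


def gen_paired_clinical(cfg: ClinicalSimConfig) -> list[PairedSample]:
    """Synthesize paired plasma/DBS samples.

    C_pla ~ lognormal; C_DBS = cf_true * C_pla * (1 + N(0, ratio_cv/100));
    Hct uniform over the validated window; samples distributed round-robin
    over subjects.
    """
    rng = np.random.default_rng(cfg.seed)
    samples: list[PairedSample] = []
    for i in range(cfg.n_samples):
        subject = f"S{(i % cfg.n_subjects) + 1:03d}"
        c_pla = float(rng.lognormal(cfg.plasma_logmean, cfg.plasma_logsd))
        noise = 1.0 + rng.normal(0.0, cfg.ratio_cv / 100.0)
        c_dbs = cfg.cf_true * c_pla * max(noise, 1e-6)
        hct = float(rng.uniform(cfg.hct_low, cfg.hct_high))
        samples.append(
            PairedSample(
                subject_id=subject,
                analyte=cfg.analyte,
                c_pla=c_pla,
                c_dbs=c_dbs,
                hct=hct,
                days_since_hct=float(rng.integers(0, 15)),
                hours_since_dose=float(rng.uniform(9.0, 26.0)),
            )
        )
    return samples


def gen_isr_pairs(
    n: int,
    cv: float,
    seed: int,
    *,
    conc_mean: float = 1000.0,
    conc_sd: float = 400.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Original/repeat concentration pairs with multiplicative run noise."""
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    mu, sig = _lognormal_params(conc_mean, conc_sd)
    original = rng.lognormal(mu, sig, n)
    repeat = original * (1.0 + rng.normal(0.0, cv / 100.0, n))
    return original, repeat
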