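"""Configuration-driven orchestration of validation and bridging runs.

`run_validation` executes calibration fitting with formal weighting
selection for every run in the calibration file, then all applicable QC
assessments (accuracy/precision, stability/dilution, recovery and
IS-normalised matrix factor, hematocrit effect for the DBS matrix) and
returns a report bundle; `run_bridging` filters paired clinical samples for
eligibility, fits the per-analyte conversion factor, and runs the full
agreement suite plus incurred-sample reanalysis.  `simulate_study` writes a
complete synthetic study under one seed so the whole pipeline can be
exercised end to end.

Report tables keep full precision in CSV; the human-readable rendering
mirrors conventional reporting precision (accuracy/CV as integers, CF to 3
decimals, slopes to 2).
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from . import io as pio
from .analytes import ANALYTE_RANGES
from .bridging import (
    HCT_RANGE,
    MAX_DAYS_SINCE_HCT,
    agreement_report,
    filter_eligible,
)
from .calibration import WEIGHTINGS, fit_weighted_line, select_weighting
from .simulate import (
    CalibSimConfig,
    clinical_config_for,
    gen_calibration_run,
    gen_isr_pairs,
    gen_paired_clinical,
    gen_qc_panel,
)
from .validation import (
    EMA_FDA_RULE,
    LLOQ_RULE,
    AcceptanceRule,
    check_acceptance,
    hct_effect_assess,
    isn_matrix_factor,
    recovery,
    summarize_qc,
)

__all__ = ["StudyConfig", "ReportBundle", "run_validation", "run_bridging", "simulate_study"]


@dataclass
class StudyConfig:
    """Flat study configuration with regulatory defaults."""

    calibration_csv: "str | None" = None
    qc_csv: "str | None" = None
    areas_csv: "str | None" = None
    paired_csv: "str | None" = None
    isr_csv: "str | None" = None
    seed: int = 0
    hct_range: tuple = HCT_RANGE
    max_days_since_hct: float = MAX_DAYS_SINCE_HCT
    acc_low: float = EMA_FDA_RULE.acc_low
    acc_high: float = EMA_FDA_RULE.acc_high
    cv_max: float = EMA_FDA_RULE.cv_max
    lloq_acc_low: float = LLOQ_RULE.acc_low
    lloq_acc_high: float = LLOQ_RULE.acc_high
    lloq_cv_max: float = LLOQ_RULE.cv_max
    weighting_candidates: tuple = WEIGHTINGS
    ftest_alpha: float = 0.01
    pct_diff_tol: float = 20.0
    pct_diff_required_fraction: float = 2.0 / 3.0
    loa_multiplier: float = 1.96
    isn_mf_cv_limit: float = 15.0
    min_r: float = 0.997

    @property
    def qc_rule(self) -> AcceptanceRule:
        return AcceptanceRule(self.acc_low, self.acc_high, self.cv_max, name="qc")

    @property
    def lloq_rule(self) -> AcceptanceRule:
        return AcceptanceRule(
            self.lloq_acc_low, self.lloq_acc_high, self.lloq_cv_max, name="lloq"
        )

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "hct_range" in raw:
            raw["hct_range"] = tuple(raw["hct_range"])
        if "weighting_candidates" in raw:
            raw["weighting_candidates"] = tuple(raw["weighting_candidates"])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)},
            default=str,
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ReportBundle:
    """Structured output of one pipeline stage."""

    stage: str
    tables: dict = field(default_factory=dict)
    exclusion_log: list = field(default_factory=list)
    overall_pass: bool = True
    provenance: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(outdir / f"{name}.csv", index=False)
        summary = {
            "stage": self.stage,
            "overall_pass": self.overall_pass,
            "n_excluded": len(self.exclusion_log),
            "provenance": self.provenance,
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))


def _provenance(config: StudyConfig) -> dict:
    return {
        "config_sha256": config.digest(),
        "seed": config.seed,
        "package_version": _pkg_version,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }


def _ap_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "analyte": r.analyte,
                "condition": r.condition,
                "nominal_ng_ml": r.nominal,
                "mean_ng_ml": r.mean_conc,
                "cv_pct": r.cv,
                "acc_pct": r.acc,
                "n": r.n,
                "is_lloq": r.is_lloq,
                "pass": r.passed,
            }
            for r in rows
        ]
    )


def run_validation(config: StudyConfig, matrix: str = "plasma") -> ReportBundle:
    """Calibration + QC validation stage for one matrix."""
    if matrix not in ("plasma", "dbs"):
        raise ValueError("matrix must be 'plasma' or 'dbs'")
    bundle = ReportBundle(stage=f"validation-{matrix}", provenance=_provenance(config))
    qc_rule, lloq_rule = config.qc_rule, config.lloq_rule

    if config.calibration_csv:
        runs = pio.read_calibration_csv(config.calibration_csv)
        fit_rows, re_rows = [], []
        for (analyte, run_id), points in runs.items():
            nominals = np.array([p.nominal for p in points])
            responses = np.array([p.response for p in points])
            lloq_n, uloq_n = nominals.min(), nominals.max()
            sel = select_weighting(
                points,
                reps_low=responses[nominals == lloq_n],
                reps_high=responses[nominals == uloq_n],
                alpha=config.ftest_alpha,
            )
            for w in config.weighting_candidates:
                f = sel.fits[w] if w in sel.fits else fit_weighted_line(points, w)
                fit_rows.append(
                    {
                        "analyte": analyte,
                        "run_id": run_id,
                        "weighting": w,
                        "chosen": w == sel.chosen,
                        "slope": f.slope_,
                        "intercept": f.intercept_,
                        "r": f.r_,
                        "ss": f.ss_,
                        "aic": f.aic_,
                        "sum_abs_re": f.sum_abs_re_,
                        "r_ok": f.r_ >= config.min_r,
                        "ftest_significant": sel.ftest_significant,
                        "rationale": sel.rationale,
                    }
                )
            chosen_fit = sel.fits[sel.chosen]
            for p, re in zip(points, chosen_fit.re_by_point_):
                re_rows.append(
                    {
                        "analyte": analyte,
                        "run_id": run_id,
                        "level_label": p.level_label,
                        "nominal_ng_ml": p.nominal,
                        "response": p.response,
                        "weighting": sel.chosen,
                        "pct_re": re,
                    }
                )
        bundle.tables["calibration_fits"] = pd.DataFrame(fit_rows)
        bundle.tables["calibration_pct_re"] = pd.DataFrame(re_rows)

    if config.qc_csv:
        qc_sets = pio.read_qc_csv(config.qc_csv)
        ap_rows, hct_sets = [], []
        for s in qc_sets:
            if s.condition.startswith("hct:"):
                hct_sets.append(s)
            else:
                ap_rows.append(check_acceptance(summarize_qc(s), qc_rule, lloq_rule=lloq_rule))
        if ap_rows:
            bundle.tables["qc_table"] = _ap_frame(ap_rows)
            bundle.overall_pass &= all(r.passed for r in ap_rows)
        if hct_sets and matrix == "dbs":  # Hct effect is a DBS-only experiment
            hct_rows, hct_pass = hct_effect_assess(hct_sets, qc_rule)
            bundle.tables["hct_effect"] = _ap_frame(hct_rows)
            bundle.overall_pass &= hct_pass

    if config.areas_csv:
        panels = pio.read_areas_csv(config.areas_csv)
        rec_rows = []
        for analyte, panel in panels.items():
            for level in sorted(panel.table["level"].unique()):
                sub = panel.table[panel.table["level"] == level]
                rec = cv = None
                if (sub["technique"] == "normal").any():
                    rec, cv = recovery(panel, level)
                mf = mf_cv = mf_ok = None
                if (sub["technique"] == "neat").any():
                    mf, mf_cv, mf_ok = isn_matrix_factor(
                        panel, level, cv_limit=config.isn_mf_cv_limit
                    )
                    bundle.overall_pass &= mf_ok
                rec_rows.append(
                    {
                        "analyte": analyte,
                        "level": level,
                        "recovery_pct": rec,
                        "recovery_cv_pct": cv,
                        "isn_mf": mf,
                        "isn_mf_cv_pct": mf_cv,
                        "isn_mf_pass": mf_ok,
                    }
                )
        bundle.tables["recovery_matrix_effect"] = pd.DataFrame(rec_rows)

    return bundle


def run_bridging(config: StudyConfig) -> ReportBundle:
    """Clinical bridging stage: eligibility, CF, agreement suite, ISR."""
    if not config.paired_csv:
        raise ValueError("paired_csv is required for the bridging stage")
    bundle = ReportBundle(stage="bridging", provenance=_provenance(config))
    samples = pio.read_paired_csv(config.paired_csv)
    eligible, log = filter_eligible(
        samples, config.hct_range, config.max_days_since_hct
    )
    bundle.exclusion_log = [
        {"subject_id": s.subject_id, "analyte": s.analyte, "reason": reason}
        for s, reason in log
    ]
    bundle.tables["exclusions"] = pd.DataFrame(
        bundle.exclusion_log, columns=["subject_id", "analyte", "reason"]
    )

    agr_rows, diff_rows = [], []
    for analyte in sorted({s.analyte for s in eligible}):
        subset = [s for s in eligible if s.analyte == analyte]
        if len(subset) < 3:
            continue  # too few eligible samples: analyte skipped
        rep = agreement_report(subset)
        agr_rows.append(
            {
                "analyte": analyte,
                "cf": rep.conversion.cf,
                "n_samples": rep.conversion.n_samples,
                "n_subjects": rep.conversion.n_subjects,
                "meets_sample_size": rep.conversion.meets_sample_size,
                "pb_slope": rep.pb.slope,
                "pb_slope_lo": rep.pb.slope_ci[0],
                "pb_slope_hi": rep.pb.slope_ci[1],
                "pb_intercept": rep.pb.intercept,
                "pb_intercept_lo": rep.pb.intercept_ci[0],
                "pb_intercept_hi": rep.pb.intercept_ci[1],
                "cusum_band": rep.pb.cusum.band,
                "lins_ccc": rep.lins_ccc,
                "ba_bias": rep.ba.bias,
                "ba_bias_lo": rep.ba.bias_ci[0],
                "ba_bias_hi": rep.ba.bias_ci[1],
                "ba_sd": rep.ba.sd,
                "ba_loa_low": rep.ba.loa_low,
                "ba_loa_high": rep.ba.loa_high,
                "spearman_r": rep.ba.spearman_r,
                "spearman_p": rep.ba.spearman_p,
                "frac_within_20": rep.pct_diff.frac_within,
                "ema_fda_pass": rep.ema_fda_pass,
            }
        )
        for s, ec, pdv in zip(subset, rep.ec_pla, rep.pct_diff.values):
            diff_rows.append(
                {
                    "analyte": analyte,
                    "subject_id": s.subject_id,
                    "c_pla_ng_ml": s.c_pla,
                    "c_dbs_ng_ml": s.c_dbs,
                    "ec_pla_ng_ml": ec,
                    "pct_diff": pdv,
                    "difference_ng_ml": ec - s.c_pla,
                    "mean_ng_ml": (ec + s.c_pla) / 2.0,
                }
            )
        bundle.overall_pass &= rep.ema_fda_pass
    bundle.tables["agreement"] = pd.DataFrame(agr_rows)
    bundle.tables["pct_diff"] = pd.DataFrame(diff_rows)

    if config.isr_csv:
        from .agreement import isr_assess

        isr = pio.read_isr_csv(config.isr_csv)
        isr_rows = []
        for (analyte, mat), grp in isr.groupby(["analyte", "matrix"], sort=True):
            res = isr_assess(
                grp["original_ng_ml"].to_numpy(),
                grp["repeat_ng_ml"].to_numpy(),
                tol=config.pct_diff_tol,
                required_fraction=config.pct_diff_required_fraction,
            )
            isr_rows.append(
                {
                    "analyte": analyte,
                    "matrix": mat,
                    "n": res.n,
                    "frac_within_20": res.frac_within,
                    "max_abs_pct_diff": max(abs(v) for v in res.values),
                    "pass": res.passed,
                }
            )
            bundle.overall_pass &= res.passed
        bundle.tables["isr"] = pd.DataFrame(isr_rows)

    return bundle


def simulate_study(outdir, seed: int = 0, ratio_cv: float = 8.0) -> dict:
    """Write a complete synthetic demo study (calibration, QC, areas, paired
    clinical samples, ISR) under one seed; returns the file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # DBS extraction yields observed per drug (methanol extraction)
    true_recovery = {"niraparib": 0.56, "rucaparib": 0.66, "olaparib": 0.93}

    runs = {}
    qc_sets = []
    area_rows = []
    for analyte in sorted(ANALYTE_RANGES):
        arange = ANALYTE_RANGES[analyte]
        for run in range(1, 4):
            cfg = CalibSimConfig(
                analyte=analyte,
                noise_model="proportional",
                noise_param=5.0,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            runs[(analyte, f"R{run}")] = gen_calibration_run(cfg)
        levels = [
            (arange.lloq, True),
            (arange.qc_low, False),
            (arange.qc_mid, False),
            (arange.qc_high, False),
        ]
        for nominal, is_lloq in levels:
            qc_sets.append(
                gen_qc_panel(
                    nominal,
                    bias=float(rng.uniform(-3, 3)),
                    cv=4.0,
                    n=5,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    analyte=analyte,
                    condition="within-run",
                    is_lloq=is_lloq,
                )
            )
            for hct in (29, 45):
                qc_sets.append(
                    gen_qc_panel(
                        nominal,
                        bias=float(rng.uniform(-5, 10)),
                        cv=4.0,
                        n=3,
                        seed=int(rng.integers(0, 2**31 - 1)),
                        analyte=analyte,
                        condition=f"hct:{hct}",
                        is_lloq=is_lloq,
                    )
                )
        # area panel: 6 donors
        true_rec = true_recovery[analyte]
        for level_name, nominal in (("L", arange.qc_low), ("H", arange.qc_high)):
            neat_area = nominal * 100.0
            for donor in range(1, 7):
                mf = rng.uniform(0.95, 1.15)
                post_a = neat_area * mf * (1 + rng.normal(0, 0.03))
                post_is = 50000.0 * mf * (1 + rng.normal(0, 0.03))
                area_rows.append(
                    dict(analyte=analyte, technique="neat", donor_id=f"D{donor}",
                         level=level_name, analyte_area=neat_area * (1 + rng.normal(0, 0.02)),
                         is_area=50000.0 * (1 + rng.normal(0, 0.02)))
                )
                area_rows.append(
                    dict(analyte=analyte, technique="post", donor_id=f"D{donor}",
                         level=level_name, analyte_area=post_a, is_area=post_is)
                )
                area_rows.append(
                    dict(analyte=analyte, technique="normal", donor_id=f"D{donor}",
                         level=level_name,
                         analyte_area=post_a * true_rec * (1 + rng.normal(0, 0.04)),
                         is_area=post_is)
                )

    paired = []
    for analyte in sorted(ANALYTE_RANGES):
        cfg = clinical_config_for(
            analyte, seed=int(rng.integers(0, 2**31 - 1)), ratio_cv=ratio_cv
        )
        paired.extend(gen_paired_clinical(cfg))

    paths = {
        "calibration_csv": outdir / "calibration.csv",
        "qc_csv": outdir / "qc.csv",
        "areas_csv": outdir / "areas.csv",
        "paired_csv": outdir / "paired.csv",
        "isr_csv": outdir / "isr.csv",
    }
    pio.write_calibration_csv(paths["calibration_csv"], runs)
    pio.write_qc_csv(paths["qc_csv"], qc_sets)
    pd.DataFrame(area_rows, columns=pio.AREAS_COLUMNS).to_csv(
        paths["areas_csv"], index=False
    )
    pio.write_paired_csv(paths["paired_csv"], paired)

    isr_frames = []
    for analyte in sorted(ANALYTE_RANGES):
        for mat in ("plasma", "dbs"):
            orig, rep = gen_isr_pairs(5, cv=5.0, seed=int(rng.integers(0, 2**31 - 1)))
            isr_frames.append(
                pd.DataFrame(
                    {
                        "sample_id": [f"{analyte[:3].upper()}{mat[0].upper()}{i+1:02d}" for i in range(5)],
                        "analyte": analyte,
                        "matrix": mat,
                        "original_ng_ml": orig,
                        "repeat_ng_ml": rep,
                    }
                )
            )
    pd.concat(isr_frames, ignore_index=True).to_csv(paths["isr_csv"], index=False)
    return {k: str(v) for k, v in paths.items()}
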