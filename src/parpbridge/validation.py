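"""Accuracy/precision summaries and EMA/FDA acceptance rules.

Every validation experiment in regulated bioanalysis reduces to the same
two summary statistics on a set of replicate measurements at a known
nominal concentration — mean accuracy (Acc% = 100 * mean / nominal) and
imprecision (CV% = 100 * sample SD / mean) — judged against a band rule:
accuracy within 85-115% and CV <= 15% for ordinary QCs, relaxed to 80-120%
and CV <= 20% at the LLOQ.  This module provides that rule engine plus the
signal-ratio experiments (extraction recovery, IS-normalised matrix factor,
selectivity/carryover thresholds, LLOQ sensitivity) and the hematocrit-effect
assessment specific to dried blood spots.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QCReplicateSet",
    "APRow",
    "AcceptanceRule",
    "AreaPanel",
    "ThresholdCheck",
    "EMA_FDA_RULE",
    "LLOQ_RULE",
    "summarize_qc",
    "check_acceptance",
    "recovery",
    "isn_matrix_factor",
    "hct_effect_assess",
    "interference_check",
    "sensitivity_check",
    "stability_or_dilution_assess",
]


@dataclass(frozen=True)
class AcceptanceRule:
    """Named accuracy band and CV cap, in percent."""

    acc_low: float
    acc_high: float
    cv_max: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.acc_low < self.acc_high:
            raise ValueError("acc_low must be < acc_high")
        if self.cv_max <= 0:
            raise ValueError("cv_max must be > 0")


#: standard QC band: accuracy 85-115%, CV <= 15%
EMA_FDA_RULE = AcceptanceRule(85.0, 115.0, 15.0, name="ema_fda_qc")
#: relaxed LLOQ band: accuracy 80-120%, CV <= 20%
LLOQ_RULE = AcceptanceRule(80.0, 120.0, 20.0, name="ema_fda_lloq")


@dataclass(frozen=True)
class QCReplicateSet:
    """Replicate measured concentrations at one nominal level."""

    analyte: str
    nominal: float
    measured: tuple
    condition: str = ""
    is_lloq: bool = False

    def __post_init__(self) -> None:
        if self.nominal <= 0:
            raise ValueError("nominal must be > 0")
        if len(self.measured) < 2:
            raise ValueError("need >= 2 replicate measurements")
        object.__setattr__(self, "measured", tuple(float(m) for m in self.measured))


@dataclass(frozen=True)
class APRow:
    """One accuracy/precision table cell."""

    analyte: str
    nominal: float
    condition: str
    mean_conc: float
    cv: float
    acc: float
    n: int
    is_lloq: bool = False
    passed: "bool | None" = None


def summarize_qc(qcs: QCReplicateSet) -> APRow:
    """Mean concentration, CV% (n-1 SD) and Acc% of a replicate set."""
    m = np.asarray(qcs.measured, dtype=float)
    mean = float(m.mean())
    sd = float(m.std(ddof=1))
    cv = 100.0 * sd / mean if mean != 0 else float("inf")
    acc = 100.0 * mean / qcs.nominal
    return APRow(
        analyte=qcs.analyte,
        nominal=qcs.nominal,
        condition=qcs.condition,
        mean_conc=mean,
        cv=cv,
        acc=acc,
        n=m.size,
        is_lloq=qcs.is_lloq,
    )


def check_acceptance(
    row: APRow,
    rule: AcceptanceRule = EMA_FDA_RULE,
    is_lloq: "bool | None" = None,
    lloq_rule: AcceptanceRule = LLOQ_RULE,
) -> APRow:
    """Apply the accuracy band and CV cap; boundary values pass.

    The LLOQ band (``lloq_rule``) applies when ``is_lloq`` (or the row's own
    flag) is set.
    """
    if is_lloq is None:
        is_lloq = row.is_lloq
    applied = lloq_rule if is_lloq else rule
    ok = applied.acc_low <= row.acc <= applied.acc_high and row.cv <= applied.cv_max
    return replace(row, passed=bool(ok), is_lloq=bool(is_lloq))


_TECHNIQUES = ("normal", "post", "neat")


@dataclass(frozen=True)
class AreaPanel:
    """Peak areas for the recovery / matrix-effect experiments.

    Wraps a long-format table with columns ``technique`` (normal extraction,
    post-extraction spike, or neat solution), ``level`` (QC level tag or
    nominal), ``analyte_area``, ``is_area``, and optionally ``donor_id`` and
    ``hct_pct``.
    """

    analyte: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"technique", "level", "analyte_area", "is_area"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"area table missing columns: {sorted(missing)}")
        bad = set(self.table["technique"].unique()) - set(_TECHNIQUES)
        if bad:
            raise ValueError(f"unknown technique tags: {sorted(bad)}")
        if (self.table[["analyte_area", "is_area"]] < 0).any().any():
            raise ValueError("peak areas must be >= 0")

    def at_level(self, level) -> pd.DataFrame:
        sub = self.table[self.table["level"] == level]
        if sub.empty:
            raise ValueError(f"no rows at level {level!r}")
        return sub


def _signal(df: pd.DataFrame, use_ratio: bool) -> np.ndarray:
    if use_ratio:
        return (df["analyte_area"] / df["is_area"]).to_numpy(dtype=float)
    return df["analyte_area"].to_numpy(dtype=float)


def recovery(
    panel: AreaPanel, level, *, use_ratio: bool = True
) -> tuple[float, float]:
    """Extraction recovery at one QC level.

    Each normal-extraction replicate signal (analyte/IS area ratio by
    default) is divided by the mean post-extraction signal; returns the mean
    and CV% of those per-replicate recoveries.
    """
    sub = panel.at_level(level)
    normal = _signal(sub[sub["technique"] == "normal"], use_ratio)
    post = _signal(sub[sub["technique"] == "post"], use_ratio)
    if normal.size < 2 or post.size < 2:
        raise ValueError("need >= 2 replicates per technique")
    post_mean = post.mean()
    if post_mean == 0:
        raise ZeroDivisionError("zero post-extraction mean: recovery undefined")
    recs = 100.0 * normal / post_mean
    return float(recs.mean()), float(100.0 * recs.std(ddof=1) / recs.mean())


def isn_matrix_factor(
    panel: AreaPanel, level, *, cv_limit: float = 15.0
) -> tuple[float, float, bool]:
    """IS-normalised matrix factor at one QC level.

    Per donor: MF_analyte = post-extraction analyte area / mean neat analyte
    area, MF_IS likewise; ISN-MF = MF_analyte / MF_IS.  Returns the mean and
    CV% across donors plus a flag for CV within ``cv_limit``.
    """
    sub = panel.at_level(level)
    post = sub[sub["technique"] == "post"]
    neat = sub[sub["technique"] == "neat"]
    if post.empty or neat.empty:
        raise ValueError("need post-extraction and neat-solution rows")
    neat_analyte = neat["analyte_area"].mean()
    neat_is = neat["is_area"].mean()
    if neat_analyte == 0 or neat_is == 0:
        raise ZeroDivisionError("zero neat-solution mean area: MF undefined")
    mf_analyte = post["analyte_area"].to_numpy(dtype=float) / neat_analyte
    mf_is = post["is_area"].to_numpy(dtype=float) / neat_is
    isn = mf_analyte / mf_is
    mean = float(isn.mean())
    cv = float(100.0 * isn.std(ddof=1) / mean) if isn.size > 1 else 0.0
    return mean, cv, bool(cv <= cv_limit)


def hct_effect_assess(
    panels: Iterable[QCReplicateSet],
    rule: AcceptanceRule = EMA_FDA_RULE,
    *,
    expected_levels: int = 4,
) -> tuple[list[APRow], bool]:
    """Hematocrit-effect table: QCs spiked at off-nominal Hct, read on the
    mid-Hct calibration curve.

    Each (Hct, level) cell is summarised and judged with the standard band
    (LLOQ cells with the LLOQ band); overall pass requires every cell to
    pass.  Each Hct arm must carry ``expected_levels`` distinct levels.
    """
    panels = list(panels)
    by_hct: dict[str, set] = {}
    for p in panels:
        by_hct.setdefault(p.condition, set()).add(p.nominal)
    for hct, levels in by_hct.items():
        if len(levels) < expected_levels:
            raise ValueError(
                f"incomplete design: {hct} has {len(levels)} levels, "
                f"expected {expected_levels}"
            )
    rows = [check_acceptance(summarize_qc(p), rule) for p in panels]
    return rows, all(r.passed for r in rows)


#: interference limits: fraction of the reference response, percent
_INTERFERENCE_LIMITS = {
    "selectivity-analyte": 20.0,
    "selectivity-IS": 5.0,
    "carryover-analyte": 20.0,
    "carryover-IS": 5.0,
}


@dataclass(frozen=True)
class ThresholdCheck:
    """A single threshold verdict (selectivity, carryover, or sensitivity)."""

    context: str
    observed_fraction: float
    limit: float
    passed: bool


def interference_check(
    blank_response: float, reference_response: float, context: str
) -> ThresholdCheck:
    """Blank-signal check at the analyte/IS retention time.

    The blank response must stay below 20% of the LLOQ response for the
    analyte and below 5% for the internal standard, both for selectivity and
    for carryover after a ULOQ injection.
    """
    if context not in _INTERFERENCE_LIMITS:
        raise ValueError(
            f"unknown context {context!r}; expected one of "
            f"{sorted(_INTERFERENCE_LIMITS)}"
        )
    if reference_response <= 0:
        raise ZeroDivisionError("reference response must be > 0")
    frac = 100.0 * blank_response / reference_response
    limit = _INTERFERENCE_LIMITS[context]
    return ThresholdCheck(context, frac, limit, bool(frac < limit))


def sensitivity_check(
    lloq_response: float,
    blank_response: float,
    *,
    snr: "float | None" = None,
    min_ratio: float = 5.0,
) -> ThresholdCheck:
    """LLOQ sensitivity: signal >= 5x the zero-sample signal, and when a
    signal-to-noise estimate is supplied it must also be >= 5."""
    if blank_response <= 0:
        ratio = float("inf") if lloq_response > 0 else 0.0
    else:
        ratio = lloq_response / blank_response
    ok = ratio >= min_ratio and (snr is None or snr >= min_ratio)
    return ThresholdCheck("sensitivity", float(ratio), min_ratio, bool(ok))


def stability_or_dilution_assess(
    qcs: Sequence[QCReplicateSet],
    rule: AcceptanceRule = EMA_FDA_RULE,
) -> list[APRow]:
    """Summarise and judge stability or dilution-integrity replicate sets.

    Dilution sets must carry measured values already multiplied by the
    dilution factor; the rule applied is the same accuracy/CV band as A&P.
    """
    return [check_acceptance(summarize_qc(q), rule) for q in qcs]
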