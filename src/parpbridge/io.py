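"""CSV schemas shared by the pipeline stages.

All inputs are plain long-format CSV.  Readers validate the header, coerce
numeric columns, and convert rows into the domain objects the statistics
operate on; writers emit the same schemas so simulated studies round-trip.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .bridging import PairedSample
from .calibration import CalibrationPoint
from .validation import AreaPanel, QCReplicateSet

__all__ = [
    "read_calibration_csv",
    "write_calibration_csv",
    "read_qc_csv",
    "write_qc_csv",
    "read_areas_csv",
    "read_paired_csv",
    "write_paired_csv",
    "read_isr_csv",
    "write_isr_csv",
]

CALIBRATION_COLUMNS = ["analyte", "run_id", "level_label", "nominal_ng_ml", "response"]
QC_COLUMNS = ["analyte", "condition", "nominal_ng_ml", "measured_ng_ml", "run_id", "replicate_id", "is_lloq"]
AREAS_COLUMNS = ["analyte", "technique", "donor_id", "level", "analyte_area", "is_area"]
PAIRED_COLUMNS = ["subject_id", "analyte", "c_pla_ng_ml", "c_dbs_ng_ml", "hct_pct", "days_since_hct", "hours_since_dose"]
ISR_COLUMNS = ["sample_id", "analyte", "matrix", "original_ng_ml", "repeat_ng_ml"]


class CsvSchemaError(ValueError):
    """Raised when a CSV is missing required columns or is empty."""


def _read(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise CsvSchemaError(f"{path}: empty file") from exc
    missing = set(required) - set(df.columns)
    if missing:
        raise CsvSchemaError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise CsvSchemaError(f"{path}: no data rows")
    return df


def read_calibration_csv(path) -> dict:
    """Calibration CSV -> {(analyte, run_id): [CalibrationPoint, ...]}."""
    df = _read(path, CALIBRATION_COLUMNS)
    runs: dict = {}
    for (analyte, run_id), grp in df.groupby(["analyte", "run_id"], sort=True):
        runs[(analyte, run_id)] = [
            CalibrationPoint(str(r.level_label), float(r.nominal_ng_ml), float(r.response))
            for r in grp.itertuples()
        ]
    return runs


def write_calibration_csv(path, runs: dict) -> None:
    rows = [
        {
            "analyte": analyte,
            "run_id": run_id,
            "level_label": p.level_label,
            "nominal_ng_ml": p.nominal,
            "response": p.response,
        }
        for (analyte, run_id), points in runs.items()
        for p in points
    ]
    pd.DataFrame(rows, columns=CALIBRATION_COLUMNS).to_csv(path, index=False)


def read_qc_csv(path) -> list[QCReplicateSet]:
    """QC CSV -> replicate sets grouped by (analyte, condition, nominal)."""
    df = _read(path, QC_COLUMNS)
    sets = []
    for (analyte, condition, nominal), grp in df.groupby(
        ["analyte", "condition", "nominal_ng_ml"], sort=True
    ):
        sets.append(
            QCReplicateSet(
                analyte=analyte,
                nominal=float(nominal),
                measured=tuple(grp["measured_ng_ml"].astype(float)),
                condition=condition,
                is_lloq=bool(grp["is_lloq"].iloc[0]),
            )
        )
    return sets


def write_qc_csv(path, sets: list[QCReplicateSet], run_id: str = "R1") -> None:
    rows = []
    for s in sets:
        for i, m in enumerate(s.measured, start=1):
            rows.append(
                {
                    "analyte": s.analyte,
                    "condition": s.condition,
                    "nominal_ng_ml": s.nominal,
                    "measured_ng_ml": m,
                    "run_id": run_id,
                    "replicate_id": i,
                    "is_lloq": s.is_lloq,
                }
            )
    pd.DataFrame(rows, columns=QC_COLUMNS).to_csv(path, index=False)


def read_areas_csv(path) -> dict:
    """Areas CSV -> {analyte: AreaPanel}."""
    df = _read(path, AREAS_COLUMNS)
    return {
        analyte: AreaPanel(analyte=analyte, table=grp.reset_index(drop=True))
        for analyte, grp in df.groupby("analyte", sort=True)
    }


def read_paired_csv(path) -> list[PairedSample]:
    df = _read(path, PAIRED_COLUMNS)
    return [
        PairedSample(
            subject_id=str(r.subject_id),
            analyte=str(r.analyte),
            c_pla=float(r.c_pla_ng_ml),
            c_dbs=float(r.c_dbs_ng_ml),
            hct=float(r.hct_pct) if not pd.isna(r.hct_pct) else float("nan"),
            days_since_hct=float(r.days_since_hct) if not pd.isna(r.days_since_hct) else float("nan"),
            hours_since_dose=float(r.hours_since_dose) if not pd.isna(r.hours_since_dose) else float("nan"),
        )
        for r in df.itertuples()
    ]


def write_paired_csv(path, samples: list[PairedSample]) -> None:
    rows = [
        {
            "subject_id": s.subject_id,
            "analyte": s.analyte,
            "c_pla_ng_ml": s.c_pla,
            "c_dbs_ng_ml": s.c_dbs,
            "hct_pct": s.hct,
            "days_since_hct": s.days_since_hct,
            "hours_since_dose": s.hours_since_dose,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=PAIRED_COLUMNS).to_csv(path, index=False)


def read_isr_csv(path) -> pd.DataFrame:
    return _read(path, ISR_COLUMNS)


def write_isr_csv(path, analyte: str, matrix: str, original, repeat) -> None:
    original = np.asarray(original)
    repeat = np.asarray(repeat)
    df = pd.DataFrame(
        {
            "sample_id": [f"{analyte[:3].upper()}{i + 1:03d}" for i in range(original.size)],
            "analyte": analyte,
            "matrix": matrix,
            "original_ng_ml": original,
            "repeat_ng_ml": repeat,
        }
    )
    df.to_csv(path, index=False)
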