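"""Analyte calibration ranges and regulatory QC placement.

The three PARP inhibitors are quantified over fixed ng/mL ranges chosen to
bracket the steady-state trough concentrations observed in patients.  QC
levels are placed from the range endpoints by the standard rule used in
regulated bioanalysis: the low QC sits at 2.55x the LLOQ, the mid QC at 34%
of the ULOQ and the high QC at 85% of the ULOQ.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "AnalyteRange",
    "ANALYTES",
    "ANALYTE_RANGES",
    "derive_qc_levels",
]

ANALYTES = ("olaparib", "rucaparib", "niraparib")

#: QC placement factors relative to the calibration range.
QC_LOW_FACTOR = 2.55  # x LLOQ
QC_MID_FRACTION = 0.34  # x ULOQ
QC_HIGH_FRACTION = 0.85  # x ULOQ

#: Calibrator level labels, highest (A) to lowest (H).
LEVEL_LABELS = ("A", "B", "C", "D", "E", "F", "G", "H")


def derive_qc_levels(
    lloq: float,
    uloq: float,
    *,
    low_factor: float = QC_LOW_FACTOR,
    mid_fraction: float = QC_MID_FRACTION,
    high_fraction: float = QC_HIGH_FRACTION,
) -> tuple[float, float, float]:
    """Place the low/mid/high QC concentrations inside a calibration range.

    Parameters
    ----------
    lloq, uloq : float
        Calibration range endpoints in ng/mL.
    low_factor, mid_fraction, high_fraction : float
        Placement rule: ``qc_low = low_factor * lloq``,
        ``qc_mid = mid_fraction * uloq``, ``qc_high = high_fraction * uloq``.

    Returns
    -------
    (qc_low, qc_mid, qc_high) : tuple of float
    """
    if not (0 < lloq < uloq):
        raise ValueError(f"invalid range: need 0 < lloq < uloq, got ({lloq}, {uloq})")
    return low_factor * lloq, mid_fraction * uloq, high_fraction * uloq


@dataclass(frozen=True)
class AnalyteRange:
    """Validated calibration range and QC placements for one analyte."""

    analyte: str
    lloq: float
    uloq: float
    qc_low: float
    qc_mid: float
    qc_high: float

    def __post_init__(self) -> None:
        if min(self.lloq, self.uloq, self.qc_low, self.qc_mid, self.qc_high) <= 0:
            raise ValueError("all concentrations must be positive")
        if not (self.lloq < self.qc_low < self.qc_mid < self.qc_high < self.uloq):
            raise ValueError(
                "QC levels must satisfy lloq < qc_low < qc_mid < qc_high < uloq"
            )

    @classmethod
    def from_range(cls, analyte: str, lloq: float, uloq: float) -> "AnalyteRange":
        """Build an :class:`AnalyteRange` with rule-derived QC placements."""
        qc_low, qc_mid, qc_high = derive_qc_levels(lloq, uloq)
        return cls(analyte, lloq, uloq, qc_low, qc_mid, qc_high)

    @property
    def calibrator_nominals(self) -> tuple[float, ...]:
        """Eight calibrator nominals, geometric-ish spacing, lowest first.

        Levels follow the fixed dilution ladder used for all three drugs:
        LLOQ x {1, 2, 5, 10, 20, 30, 40, 50}.
        """
        multipliers = (1, 2, 5, 10, 20, 30, 40, 50)
        return tuple(self.lloq * m for m in multipliers)


ANALYTE_RANGES: dict[str, AnalyteRange] = {
    "olaparib": AnalyteRange.from_range("olaparib", 140.0, 7000.0),
    "rucaparib": AnalyteRange.from_range("rucaparib", 100.0, 5000.0),
    "niraparib": AnalyteRange.from_range("niraparib", 60.0, 3000.0),
}
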