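"""Point-to-point 3D morphometrics and the calibration-error report.

Morphometric measurements (head width as the distance between the eyes at
its widest point, eye width as the largest visible eye diameter, ...) are
Euclidean distances between picked 3D points, summarised as mean +/- sample
s.d. over at least three repeats from different perspectives.  The
calibration report mirrors the instrument validation statistic: distances
measured on a known target must err, on average, by less than 2% of the
distance measured.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "distance3d",
    "Measurement",
    "measurement_stats",
    "CalibrationReport",
    "calibration_report",
    "summarize_measurements",
]


def distance3d(p1: np.ndarray, p2: np.ndarray) -> float:
    """Euclidean distance in mm between two 3D points."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != (3,) or p2.shape != (3,):
        raise ValueError("points must be 3-vectors")
    if not (np.all(np.isfinite(p1)) and np.all(np.isfinite(p2))):
        raise ValueError("points must be finite")
    return float(np.sqrt(np.sum((p1 - p2) ** 2)))


@dataclass(frozen=True)
class Measurement:
    """One labelled point-to-point measurement."""

    label: str
    p1: tuple[float, float, float]
    p2: tuple[float, float, float]
    frame: int

    @property
    def value_mm(self) -> float:
        v = distance3d(np.asarray(self.p1), np.asarray(self.p2))
        if v <= 0:
            raise ValueError("measurement endpoints must be distinct")
        return v


def measurement_stats(values: np.ndarray) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation of repeated measurements.

    At least three repeats from different perspectives are required.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError(
            f"need at least 3 repeated measurements, got {values.size}"
        )
    return float(np.mean(values)), float(np.std(values, ddof=1))


def summarize_measurements(measurements: list[Measurement]) -> pd.DataFrame:
    """Mean +/- s.d. per label from repeated picks (>= 3 repeats each)."""
    rows = []
    df = pd.DataFrame(
        [{"label": m.label, "value_mm": m.value_mm} for m in measurements]
    )
    for label, grp in df.groupby("label", sort=True):
        mean, sd = measurement_stats(grp["value_mm"].to_numpy())
        rows.append({"label": label, "n": len(grp), "mean_mm": mean, "sd_mm": sd})
    return pd.DataFrame(rows, columns=["label", "n", "mean_mm", "sd_mm"])


@dataclass
class CalibrationReport:
    per_pair_error_pct: np.ndarray
    mean_error_pct: float
    passed: bool  # strict: mean error < 2%

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"error_pct": self.per_pair_error_pct})


def calibration_report(
    measured_mm: np.ndarray, known_mm: np.ndarray, gate_pct: float = 2.0
) -> CalibrationReport:
    """Percentage errors of measured vs known distances.

    ``error_i = |measured_i - known_i| / known_i * 100``; the report passes
    when the mean error is strictly below ``gate_pct`` (default 2%).
    """
    measured = np.asarray(measured_mm, dtype=float)
    known = np.asarray(known_mm, dtype=float)
    if measured.shape != known.shape:
        raise ValueError("measured and known lists must have equal length")
    if np.any(known <= 0):
        raise ValueError("known distances must be positive")
    err = np.abs(measured - known) / known * 100.0
    mean = float(np.mean(err))
    return CalibrationReport(err, mean, mean < gate_pct)
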