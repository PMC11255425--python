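"""Flow-cell calibration: electrode sensitivity from dopamine bolus responses.

Before implantation each electrode array is placed in a flow cell and pulsed
with three boluses at each of four dopamine concentrations (0.5, 1, 2 and
4 µM).  During each bolus the oxidation current is sampled three times — at
the onset peak, just before the washout falloff, and midway between the two —
and the three samples are averaged.  Per-concentration means define a
calibration curve whose slope (nA/µM, fit through the origin) is the
electrode's calibration factor, later used to convert chemometric dopamine
current into concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationError",
    "CalibrationCurve",
    "BolusMeasurement",
    "measure_bolus_response",
    "average_bolus_means",
    "fit_calibration_curve",
    "apply_calibration",
    "uncalibrate",
    "DEFAULT_CONCENTRATIONS_UM",
]

DEFAULT_CONCENTRATIONS_UM = (0.5, 1.0, 2.0, 4.0)


class CalibrationError(ValueError):
    """Calibration fit failed (non-positive or non-monotone response)."""


@dataclass(frozen=True)
class BolusMeasurement:
    """Three-point sampling of a single bolus window."""

    onset_peak_nA: float
    pre_falloff_nA: float
    midpoint_nA: float
    mean_nA: float
    valid: bool


@dataclass(frozen=True)
class CalibrationCurve:
    """Per-electrode (or per-cohort device) calibration line through the origin."""

    concentrations_uM: np.ndarray
    mean_currents_nA: np.ndarray
    factor_nA_per_uM: float
    fit_residual_nA: float

    def __post_init__(self) -> None:
        if self.factor_nA_per_uM <= 0:
            raise CalibrationError("calibration factor must be positive")
        c = np.asarray(self.concentrations_uM, dtype=float)
        y = np.asarray(self.mean_currents_nA, dtype=float)
        order = np.argsort(c)
        tol = 0.01 * np.max(np.abs(y)) if y.size else 0.0
        if np.any(np.diff(y[order]) < -tol):
            raise CalibrationError(
                "mean currents are not non-decreasing in concentration"
            )


def measure_bolus_response(
    times: np.ndarray,
    current_nA: np.ndarray,
    window: "tuple[float, float]",
    plateau_frac: float = 0.9,
    min_plateau_samples: int = 3,
) -> BolusMeasurement:
    """Sample one bolus window at its three landmarks and average them.

    Landmarks (the sampling instants the protocol names, made operational):
    the onset peak is the maximum in the first third of the window; the
    pre-falloff point is the last sample still above ``plateau_frac`` of the
    plateau level (median of the window); the midpoint is the sample halfway
    between those two instants.  Windows without at least
    ``min_plateau_samples`` near the plateau are flagged invalid.
    """
    times = np.asarray(times, dtype=float)
    current = np.asarray(current_nA, dtype=float)
    mask = (times >= window[0]) & (times <= window[1])
    seg = current[mask]
    if seg.size < 3:
        warnings.warn("bolus window holds fewer than 3 samples; flagged", stacklevel=2)
        return BolusMeasurement(np.nan, np.nan, np.nan, np.nan, False)

    plateau = float(np.median(seg))
    n_plateau = int(np.sum(np.abs(seg - plateau) <= 0.1 * abs(plateau)))
    if plateau <= 0 or n_plateau < min_plateau_samples:
        warnings.warn("bolus window has no detectable plateau; flagged", stacklevel=2)
        return BolusMeasurement(np.nan, np.nan, np.nan, np.nan, False)

    first_third = max(1, seg.size // 3)
    i_peak = int(np.argmax(seg[:first_third]))
    above = np.flatnonzero(seg >= plateau_frac * plateau)
    i_falloff = int(above[-1]) if above.size else seg.size - 1
    if i_falloff <= i_peak:
        i_falloff = seg.size - 1
    i_mid = (i_peak + i_falloff) // 2

    onset_peak = float(seg[i_peak])
    pre_falloff = float(seg[i_falloff])
    midpoint = float(seg[i_mid])
    return BolusMeasurement(
        onset_peak, pre_falloff, midpoint,
        (onset_peak + pre_falloff + midpoint) / 3.0, True,
    )


def average_bolus_means(table: pd.DataFrame) -> pd.Series:
    """Mean current per concentration over its (valid) boluses.

    ``table`` columns: ``concentration_uM, bolus_id, mean_current_nA`` — the
    tabular interchange format for calibration runs.
    """
    valid = table.dropna(subset=["mean_current_nA"])
    return valid.groupby("concentration_uM")["mean_current_nA"].mean()


def fit_calibration_curve(
    concentrations_uM,
    mean_currents_nA,
    allow_single: bool = False,
    intercept: bool = False,
) -> CalibrationCurve:
    """Least-squares calibration line; the slope is the calibration factor.

    By default the line is constrained through the origin (zero dopamine
    produces zero faradaic current): ``factor = Σ(c·i) / Σ(c²)``.  With
    ``intercept=True`` an ordinary two-parameter line is fit and only its
    slope is kept as the factor.
    """
    c = np.asarray(concentrations_uM, dtype=float)
    y = np.asarray(mean_currents_nA, dtype=float)
    ok = np.isfinite(c) & np.isfinite(y)
    c, y = c[ok], y[ok]
    if c.size == 0:
        raise CalibrationError("no valid calibration points")
    if c.size == 1 and not allow_single:
        raise CalibrationError(
            "a single concentration cannot define a curve (set allow_single=True "
            "to accept a one-point through-origin factor)"
        )
    if intercept and c.size >= 2:
        slope, b = np.polyfit(c, y, 1)
        resid = y - (slope * c + b)
    else:
        slope = float(np.sum(c * y) / np.sum(c * c))
        resid = y - slope * c
    if slope <= 0:
        raise CalibrationError(f"non-positive calibration slope ({slope:.3g} nA/µM)")
    return CalibrationCurve(
        concentrations_uM=c,
        mean_currents_nA=y,
        factor_nA_per_uM=float(slope),
        fit_residual_nA=float(np.sqrt(np.mean(resid**2))),
    )


def apply_calibration(da_current_nA, factor_nA_per_uM: float) -> np.ndarray:
    """Convert a dopamine current trace (nA) to concentration in nanomolar."""
    if factor_nA_per_uM <= 0:
        raise CalibrationError("calibration factor must be positive")
    return np.asarray(da_current_nA, dtype=float) / factor_nA_per_uM * 1000.0


def uncalibrate(concentration_nM, factor_nA_per_uM: float) -> np.ndarray:
    """Inverse of :func:`apply_calibration` (nM back to nA)."""
    if factor_nA_per_uM <= 0:
        raise CalibrationError("calibration factor must be positive")
    return np.asarray(concentration_nM, dtype=float) / 1000.0 * factor_nA_per_uM
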