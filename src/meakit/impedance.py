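"""Electrode impedance calibration and summary statistics.

The acquisition hardware reports electrode impedances that deviate from
truth by an approximately affine, frequency-dependent error. Measuring
known reference resistors (1, 10 and 100 kOhm) at each target frequency
(100, 1000 and 7500 Hz by default) yields a per-frequency linear
calibration curve ``measured = slope * true + intercept``; inverting it
recovers the actual impedance from the instrument reading.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError

DEFAULT_FREQUENCIES_HZ = (100.0, 1000.0, 7500.0)
REFERENCE_RESISTORS_KOHM = (1.0, 10.0, 100.0)
DEFAULT_R_MIN = 0.98


@dataclass
class CalibrationCurve:
    """Per-frequency linear fit of measured versus true impedance."""

    frequency: float  # Hz
    slope: float
    intercept: float  # kOhm
    r: float  # Pearson correlation of the fit
    n_points: int
    low_quality: bool = False  # r fell below r_min at fit time

    @property
    def r_squared(self) -> float:
        return self.r**2


def fit_calibration(
    true_kohm,
    measured_kohm,
    frequency: float,
    r_min: float = DEFAULT_R_MIN,
) -> CalibrationCurve:
    """Ordinary least-squares fit ``measured = slope * true + intercept``.

    ``r`` is the Pearson correlation of the pairs; a fit with
    ``r < r_min`` is flagged and warned about but not rejected. Fewer than
    two pairs, or identical true values, are errors.
    """
    true = np.asarray(true_kohm, dtype=float)
    measured = np.asarray(measured_kohm, dtype=float)
    if true.shape != measured.shape:
        raise ParameterError("true and measured arrays differ in length")
    if true.size < 2:
        raise ParameterError("calibration needs at least 2 reference pairs")
    if np.ptp(true) == 0:
        raise ParameterError("singular fit: all reference values identical")
    fit = sps.linregress(true, measured)
    r = float(fit.rvalue)
    low = abs(r) < r_min
    if low:
        warnings.warn(
            f"calibration at {frequency:g} Hz: |r| = {abs(r):.4f} < {r_min}",
            stacklevel=2,
        )
    return CalibrationCurve(
        frequency=float(frequency),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=r,
        n_points=int(true.size),
        low_quality=low,
    )


def apply_calibration(curve: CalibrationCurve, raw_kohm):
    """Invert the calibration: ``corrected = (raw - intercept) / slope``.

    Applying a curve fitted on undistorted data is the identity.
    """
    if abs(curve.slope) < 1e-12:
        raise ParameterError("calibration slope is (numerically) zero")
    raw = np.asarray(raw_kohm, dtype=float)
    corrected = (raw - curve.intercept) / curve.slope
    return float(corrected) if np.isscalar(raw_kohm) else corrected


def calibrate_table(
    measurements: pd.DataFrame, curves: dict[float, CalibrationCurve]
) -> pd.DataFrame:
    """Add a ``corrected_kohm`` column to a raw measurement table.

    ``measurements`` needs columns ``electrode_id, frequency_hz, raw_kohm``;
    each row is corrected with the curve for its frequency.
    """
    out = measurements.reset_index(drop=True).copy()
    corrected = np.empty(len(out))
    for f, sub in out.groupby("frequency_hz"):
        if float(f) not in curves:
            raise ParameterError(f"no calibration curve for frequency {f} Hz")
        corrected[sub.index] = apply_calibration(
            curves[float(f)], sub["raw_kohm"].to_numpy()
        )
    out["corrected_kohm"] = corrected
    return out


def summarize_impedance(
    measurements: pd.DataFrame, value_col: str = "corrected_kohm"
) -> pd.DataFrame:
    """Per-frequency mean, sample SD, n and max relative deviation.

    The max relative deviation is ``max |x - mean| / mean`` within each
    frequency. A single measurement at a frequency yields ``sd = 0``.
    """
    if value_col not in measurements.columns:
        raise ParameterError(f"measurement table has no column {value_col!r}")
    rows = []
    for f, sub in measurements.groupby("frequency_hz"):
        x = sub[value_col].to_numpy(dtype=float)
        # two-pass with compensated summation: identical inputs summarize
        # to their exact common value
        mean = math.fsum(x) / x.size
        sd = (
            math.sqrt(math.fsum((x - mean) ** 2) / (x.size - 1))
            if x.size > 1
            else 0.0
        )
        max_rel = float(np.abs(x - mean).max() / mean) if mean != 0 else np.nan
        rows.append((float(f), mean, sd, int(x.size), max_rel))
    return pd.DataFrame(
        rows,
        columns=["frequency_hz", "mean_kohm", "sd_kohm", "n", "max_rel_deviation"],
    ).sort_values("frequency_hz", ignore_index=True)


def fit_calibration_table(
    pairs: pd.DataFrame, r_min: float = DEFAULT_R_MIN
) -> dict[float, CalibrationCurve]:
    """Fit one calibration curve per frequency from a reference-pair table
    with columns ``frequency_hz, true_kohm, raw_kohm``."""
    curves = {}
    for f, sub in pairs.groupby("frequency_hz"):
        curves[float(f)] = fit_calibration(
            sub["true_kohm"], sub["raw_kohm"], float(f), r_min=r_min
        )
    return curves
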