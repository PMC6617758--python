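"""Validation metrics for predicted knee contact forces.

Predicted and reference (instrumented-implant style) records are
compared on a common 0-100% gait-cycle axis in body-weight units:
root-mean-square error, coefficient of determination, and magnitude and
timing of the two characteristic stance peaks (weight acceptance in
early stance, push-off in late stance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .errors import ParameterError

__all__ = ["ValidationStats", "resample_percent_cycle", "find_peaks", "compare"]

#: cycle windows searched for the two stance peaks (% cycle)
FIRST_PEAK_WINDOW = (0.0, 30.0)
SECOND_PEAK_WINDOW = (30.0, 65.0)


@dataclass(frozen=True)
class ValidationStats:
    """Agreement between a predicted and a reference contact-force record."""

    rmse: float                      # BW
    r_squared: float
    pred_peaks: tuple                # ((mag BW, % cycle), (mag BW, % cycle))
    ref_peaks: tuple
    peak_magnitude_diff: tuple       # pred - ref, per peak (BW)
    peak_timing_diff: tuple          # pred - ref, per peak (% cycle)

    def to_dict(self) -> dict:
        return asdict(self)


def resample_percent_cycle(series, heel_strikes) -> np.ndarray:
    """Resample one gait cycle onto the 0,1,...,100% axis.

    ``heel_strikes`` are the two sample indices delimiting the cycle;
    linear interpolation is used and the endpoints reproduce the
    heel-strike samples exactly.  Multi-column series are resampled
    column-wise.
    """
    y = np.asarray(series, dtype=float)
    i0, i1 = int(heel_strikes[0]), int(heel_strikes[1])
    if i1 <= i0:
        raise ParameterError("heel strikes must be in increasing order")
    if i0 < 0 or i1 >= len(y):
        raise ParameterError("heel-strike index outside series")
    x = np.linspace(0.0, 100.0, i1 - i0 + 1)
    xq = np.arange(101.0)
    if y.ndim == 1:
        return np.interp(xq, x, y[i0:i1 + 1])
    return np.column_stack([np.interp(xq, x, y[i0:i1 + 1, j]) for j in range(y.shape[1])])


def _window_max(record: np.ndarray, window) -> tuple:
    lo, hi = window
    idx = np.arange(len(record))
    percent = idx * 100.0 / (len(record) - 1)
    mask = (percent >= lo) & (percent <= hi)
    sub = record[mask]
    k = int(np.argmax(sub))
    return float(sub[k]), float(percent[mask][k])


def find_peaks(record, first_window=FIRST_PEAK_WINDOW,
               second_window=SECOND_PEAK_WINDOW) -> tuple:
    """Magnitude (BW) and timing (% cycle) of the two stance peaks.

    Each peak is the maximum of the record inside its cycle window.  A
    record with no interior maximum (monotone) triggers a warning and
    the global maximum is reported for both peaks.
    """
    rec = np.asarray(record, dtype=float)
    diffs = np.diff(rec)
    if np.all(diffs >= 0) or np.all(diffs <= 0):
        warnings.warn("record is monotone; reporting the global maximum twice",
                      stacklevel=2)
        k = int(np.argmax(rec))
        peak = (float(rec[k]), k * 100.0 / (len(rec) - 1))
        return peak, peak
    return _window_max(rec, first_window), _window_max(rec, second_window)


def compare(pred, ref) -> ValidationStats:
    """RMSE, R-squared and per-peak magnitude/timing differences.

    R-squared is computed against the variance of the reference record:
    ``1 - SS_res / SS_tot`` with ``SS_tot`` about the reference mean.
    Both records must be on the 101-sample cycle axis.
    """
    p = np.asarray(pred, dtype=float)
    r = np.asarray(ref, dtype=float)
    if len(p) != 101 or len(r) != 101:
        raise ParameterError("records must have exactly 101 samples")
    diff = p - r
    rmse = float(np.sqrt(np.mean(diff**2)))
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 - float(np.sum(diff**2)) / ss_tot if ss_tot > 0 else float("nan")
    pp = find_peaks(p)
    rp = find_peaks(r)
    return ValidationStats(
        rmse=rmse,
        r_squared=r2,
        pred_peaks=pp,
        ref_peaks=rp,
        peak_magnitude_diff=tuple(pp[i][0] - rp[i][0] for i in range(2)),
        peak_timing_diff=tuple(pp[i][1] - rp[i][1] for i in range(2)),
    )
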