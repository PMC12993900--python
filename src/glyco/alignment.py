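"""Sensor-blood time-shift estimation, hematocrit conversion, Bland-Altman.

Sign convention (important): a positive lag means the CGM trace TRAILS blood
glucose, i.e. ``cgm(t) ~= blood(t - lag)`` — the physiological interstitial
delay.  ``shift_trace(trace, lag)`` moves values towards LATER indices for
positive lag (padding the start with the first value), so aligning an
estimated CGM trace onto blood time uses ``shift_trace(cgm, -lag)``, which
is what :func:`estimate_lag` stores in ``AlignmentResult.shifted_trace``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .io_formats import BloodSampleSeries, GlucoseTrace

__all__ = [
    "AlignmentResult",
    "BlandAltman",
    "estimate_lag",
    "shift_trace",
    "plasma_to_blood",
    "convert_series_to_blood",
    "bland_altman",
    "pair_on_grid",
]


@dataclass(frozen=True)
class AlignmentResult:
    lag: int  # minutes; positive = CGM lags blood
    peak_correlation: float
    shifted_trace: GlucoseTrace


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    n_pairs: int


def _common_grid(a: GlucoseTrace, b: GlucoseTrace) -> tuple[np.ndarray, np.ndarray]:
    """Values of both traces restricted to their shared 1-min timestamps."""
    start = max(a.times[0], b.times[0])
    end = min(a.times[-1], b.times[-1])
    if end <= start:
        raise ValueError("traces do not overlap in time")
    wa, wb = a.window(start, end), b.window(start, end)
    if len(wa) != len(wb) or not (wa.times == wb.times).all():
        raise ValueError("traces are not on a common 1-min grid; resample first")
    step = np.diff(wa.minutes)
    if len(step) and not np.allclose(step, 1.0):
        raise ValueError("estimate_lag expects 1-min resampled traces")
    return wa.glucose, wb.glucose


def estimate_lag(
    cgm_1min: GlucoseTrace, blood_1min: GlucoseTrace, max_lag: int = 60
) -> AlignmentResult:
    """Estimate the whole-minute lag of the CGM trace behind blood glucose.

    Both series are restricted to their common 1-min grid, mean-centered,
    and cross-correlated in the frequency domain; the lag is the argmax of
    the normalized cross-correlation over ``[-max_lag, +max_lag]`` minutes.

    Raises
    ------
    ValueError
        If either series is constant over the overlap (undefined
        correlation) or the overlap is shorter than ``4 * max_lag`` minutes.
    """
    x, y = _common_grid(cgm_1min, blood_1min)  # x = CGM, y = blood
    n = len(x)
    if n < 4 * max_lag:
        raise ValueError(
            f"overlap of {n} min is too short; need at least {4 * max_lag} min"
        )
    x = x - x.mean()
    y = y - y.mean()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("constant series: cross-correlation undefined")
    corr = signal.correlate(x, y, mode="full", method="fft") / (nx * ny)
    lags = signal.correlation_lags(n, n, mode="full")
    keep = np.abs(lags) <= max_lag
    corr, lags = corr[keep], lags[keep]
    best = int(np.argmax(corr))
    lag = int(lags[best])
    return AlignmentResult(
        lag=lag,
        peak_correlation=float(corr[best]),
        shifted_trace=shift_trace(cgm_1min, -lag),
    )


def shift_trace(trace: GlucoseTrace, lag: int) -> GlucoseTrace:
    """Translate a 1-min-grid trace by ``lag`` minutes, edge-padding.

    Positive lag moves values to later timestamps; vacated positions take
    the first (or, for negative lag, the last) original value.  Length and
    timestamps are unchanged.
    """
    step = np.diff(trace.minutes)
    if len(step) and not np.allclose(step, 1.0):
        raise ValueError("shift_trace expects a 1-min grid")
    k = int(lag)
    n = len(trace)
    if abs(k) >= n:
        raise ValueError(f"|lag| = {abs(k)} exceeds trace length {n}")
    values = trace.glucose
    if k > 0:
        shifted = np.concatenate([np.full(k, values[0]), values[:-k]])
    elif k < 0:
        shifted = np.concatenate([values[-k:], np.full(-k, values[-1])])
    else:
        shifted = values.copy()
    return trace.replace(glucose=shifted, source="shifted")


def plasma_to_blood(plasma, hematocrit: float):
    """Convert plasma glucose to whole-blood-equivalent glucose.

    Porcine erythrocytes are impermeable to glucose, so whole-blood glucose
    is confined to the plasma fraction: ``blood = plasma * (1 - hematocrit)``.
    """
    if not 0.0 < hematocrit < 1.0:
        # hematocrit 0 is allowed only as the formal limit blood == plasma
        if hematocrit == 0.0:
            return np.asarray(plasma, dtype=float) * 1.0
        raise ValueError(f"hematocrit {hematocrit} outside (0, 1)")
    return np.asarray(plasma, dtype=float) * (1.0 - hematocrit)


def convert_series_to_blood(series: BloodSampleSeries) -> BloodSampleSeries:
    """Hematocrit-convert a plasma series to blood-equivalent units."""
    if series.medium != "plasma":
        raise ValueError("series is already blood-equivalent")
    return BloodSampleSeries(
        animal_id=series.animal_id,
        times=series.times,
        plasma_glucose=plasma_to_blood(series.plasma_glucose, series.hematocrit),
        hematocrit=series.hematocrit,
        medium="blood_equivalent",
    )


def bland_altman(a, b) -> BlandAltman:
    """Bland-Altman agreement of two matched measurement vectors.

    Differences are ``a - b``; bias is their mean, limits of agreement are
    ``bias +/- 1.96 * sd`` with the sample (n-1) SD.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("methods must supply matched vectors of equal length")
    if len(a) < 2:
        raise ValueError(f"need at least 2 pairs, got {len(a)}")
    diffs = a - b
    bias = float(diffs.mean())
    sd = float(np.std(diffs, ddof=1))
    return BlandAltman(
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        n_pairs=len(a),
    )


def pair_on_grid(
    trace_1min: GlucoseTrace, sample_times: pd.DatetimeIndex, sample_values
) -> tuple[np.ndarray, np.ndarray]:
    """Match sparse samples to the nearest 1-min grid point of a trace.

    Returns ``(trace_values, sample_values)`` for samples whose nearest grid
    point lies within the trace span; samples outside are dropped.
    """
    sample_times = pd.DatetimeIndex(sample_times)
    sample_values = np.asarray(sample_values, dtype=float)
    idx = trace_1min.times.get_indexer(sample_times, method="nearest")
    keep = (sample_times >= trace_1min.times[0]) & (sample_times <= trace_1min.times[-1])
    return trace_1min.glucose[idx[keep]], sample_values[keep]
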