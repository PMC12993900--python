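"""Baseline-band definition and peak/nadir excursion detection.

A per-animal baseline band is the mean +/- one sample SD of glucose over a
reference window (by default the night preceding the analysed day).  Within
an analysis window, maximal runs of consecutive samples strictly above the
band's upper edge are peaks, runs strictly below the lower edge are nadirs.
Each excursion carries its extremum, its duration (first to last run sample)
and the trapezoidal area between the trace and the crossed band edge over
the run samples.  Per-window summaries mirror the usual CGM reporting:
counts, total durations and AUCs, window extrema, the sharpest peak/nadir
and band-time fractions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta

import numpy as np
import pandas as pd

from .io_formats import GlucoseTrace, StudyDesign

__all__ = [
    "BaselineBand",
    "Excursion",
    "PeriodMetrics",
    "DegenerateBandWarning",
    "compute_baseline",
    "detect_excursions",
    "summarize_period",
    "resolve_windows",
]

Window = tuple[pd.Timestamp, pd.Timestamp]


class DegenerateBandWarning(UserWarning):
    """Emitted when the baseline band has zero width (sd = 0)."""


@dataclass(frozen=True)
class BaselineBand:
    """Reference band: mean +/- one sample SD over a stated window."""

    mean: float
    sd: float
    reference_window: Window
    animal_id: str = ""

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @property
    def lower(self) -> float:
        return self.mean - self.sd

    @property
    def upper(self) -> float:
        return self.mean + self.sd

    def shifted(self, offset: float) -> "BaselineBand":
        return BaselineBand(self.mean + offset, self.sd, self.reference_window, self.animal_id)


@dataclass(frozen=True)
class Excursion:
    """One maximal run of samples outside the baseline band."""

    kind: str  # "peak" or "nadir"
    start: pd.Timestamp
    end: pd.Timestamp
    extremum_value: float
    extremum_time: pd.Timestamp
    auc: float  # mg/dL*min beyond the crossed band edge

    def __post_init__(self) -> None:
        if self.kind not in ("peak", "nadir"):
            raise ValueError(f"kind must be 'peak' or 'nadir', got {self.kind!r}")
        if self.end < self.start:
            raise ValueError("excursion end precedes start")
        if self.auc < 0:
            raise ValueError("auc must be non-negative")

    @property
    def duration(self) -> float:
        """Minutes between the first and last run sample."""
        return (self.end - self.start).total_seconds() / 60.0


@dataclass(frozen=True)
class PeriodMetrics:
    """Per-window excursion summary (one row of the tidy metric table)."""

    period: str
    window: Window
    n_peaks: int
    n_nadirs: int
    total_peak_duration: float
    total_nadir_duration: float
    total_peak_auc: float
    total_nadir_auc: float
    max_glucose: float
    min_glucose: float
    sharpest_peak: Excursion | None
    sharpest_nadir: Excursion | None
    frac_above: float
    frac_below: float
    frac_within_band: float
    relative_range_pct: float

    def as_dict(self) -> dict[str, float]:
        """Flatten to scalar metrics (tidy-table row)."""
        sp, sn = self.sharpest_peak, self.sharpest_nadir
        return {
            "n_peaks": self.n_peaks,
            "n_nadirs": self.n_nadirs,
            "total_peak_duration": self.total_peak_duration,
            "total_nadir_duration": self.total_nadir_duration,
            "total_peak_auc": self.total_peak_auc,
            "total_nadir_auc": self.total_nadir_auc,
            "max_glucose": self.max_glucose,
            "min_glucose": self.min_glucose,
            "sharpest_peak_duration": sp.duration if sp else math.nan,
            "sharpest_peak_auc": sp.auc if sp else math.nan,
            "sharpest_nadir_duration": sn.duration if sn else math.nan,
            "sharpest_nadir_auc": sn.auc if sn else math.nan,
            "frac_above": self.frac_above,
            "frac_below": self.frac_below,
            "frac_within_band": self.frac_within_band,
            "relative_range_pct": self.relative_range_pct,
        }


def compute_baseline(
    trace: GlucoseTrace, window: Window, min_samples: int = 10
) -> BaselineBand:
    """Mean +/- sample SD of observed glucose over ``window`` (inclusive).

    Raises
    ------
    ValueError
        If fewer than ``min_samples`` observed samples fall in the window.
    """
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    sub = trace.window(start, end)
    values = sub.glucose[~sub.missing]
    if len(values) < min_samples:
        raise ValueError(
            f"baseline window [{start}, {end}] holds {len(values)} observed samples, "
            f"need at least {min_samples}"
        )
    return BaselineBand(
        mean=float(np.mean(values)),
        sd=float(np.std(values, ddof=1)),
        reference_window=(start, end),
        animal_id=trace.animal_id,
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, stop) index pairs."""
    out = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return out
    start = prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            out.append((start, prev + 1))
            start = i
        prev = i
    out.append((start, prev + 1))
    return out


def _excursion_from_run(
    kind: str, times: pd.DatetimeIndex, minutes: np.ndarray, values: np.ndarray, edge: float
) -> Excursion:
    excess = np.abs(values - edge)
    auc = float(np.trapezoid(excess, minutes)) if len(values) > 1 else 0.0
    i_ext = int(np.argmax(values)) if kind == "peak" else int(np.argmin(values))
    return Excursion(
        kind=kind,
        start=times[0],
        end=times[-1],
        extremum_value=float(values[i_ext]),
        extremum_time=times[i_ext],
        auc=auc,
    )


def detect_excursions(
    trace: GlucoseTrace, band: BaselineBand, window: Window | None = None
) -> list[Excursion]:
    """Detect peaks and nadirs of a repaired trace relative to a band.

    Peaks are maximal runs strictly above ``band.upper``; nadirs strictly
    below ``band.lower``.  AUC is the trapezoidal integral of the excess
    beyond the crossed band edge over the run samples only (no crossing-point
    extrapolation); a single-sample run has duration 0 and AUC 0.  The
    returned list is ordered by start time.
    """
    if trace.missing.any():
        raise ValueError("detect_excursions requires a repaired trace")
    if window is not None:
        sub = trace.window(pd.Timestamp(window[0]), pd.Timestamp(window[1]))
    else:
        sub = trace
    if band.sd == 0.0:
        warnings.warn(
            "baseline band has zero width; every off-mean sample starts a run",
            DegenerateBandWarning,
            stacklevel=2,
        )
    times, minutes, values = sub.times, sub.minutes, sub.glucose
    excursions = []
    for kind, mask, edge in (
        ("peak", values > band.upper, band.upper),
        ("nadir", values < band.lower, band.lower),
    ):
        for start, stop in _runs(mask):
            excursions.append(
                _excursion_from_run(
                    kind, times[start:stop], minutes[start:stop], values[start:stop], edge
                )
            )
    excursions.sort(key=lambda e: e.start)
    return excursions


def _sharpest(excursions: list[Excursion], kind: str) -> Excursion | None:
    """Most extreme excursion of a kind; ties go to the earlier one."""
    members = [e for e in excursions if e.kind == kind]
    if not members:
        return None
    if kind == "peak":
        best = max(members, key=lambda e: (e.extremum_value, -e.start.value))
    else:
        best = min(members, key=lambda e: (e.extremum_value, e.start.value))
    return best


def summarize_period(
    excursions: list[Excursion],
    trace: GlucoseTrace,
    band: BaselineBand,
    window: Window,
    period: str = "window",
) -> PeriodMetrics:
    """Summarize a window's excursions into a :class:`PeriodMetrics` row.

    Band-time fractions are sample-count fractions of the window; the
    relative range is ``100 * (max - min) / max`` over the window.
    """
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    sub = trace.window(start, end)
    values = sub.glucose[~sub.missing]
    if len(values) == 0:
        raise ValueError(f"window [{start}, {end}] holds no observed samples")
    peaks = [e for e in excursions if e.kind == "peak"]
    nadirs = [e for e in excursions if e.kind == "nadir"]
    n = len(values)
    n_above = int((values > band.upper).sum())
    n_below = int((values < band.lower).sum())
    gmax, gmin = float(values.max()), float(values.min())
    return PeriodMetrics(
        period=period,
        window=(start, end),
        n_peaks=len(peaks),
        n_nadirs=len(nadirs),
        total_peak_duration=float(sum(e.duration for e in peaks)),
        total_nadir_duration=float(sum(e.duration for e in nadirs)),
        total_peak_auc=float(sum(e.auc for e in peaks)),
        total_nadir_auc=float(sum(e.auc for e in nadirs)),
        max_glucose=gmax,
        min_glucose=gmin,
        sharpest_peak=_sharpest(excursions, "peak"),
        sharpest_nadir=_sharpest(excursions, "nadir"),
        frac_above=n_above / n,
        frac_below=n_below / n,
        frac_within_band=(n - n_above - n_below) / n,
        relative_range_pct=100.0 * (gmax - gmin) / gmax if gmax != 0 else math.nan,
    )


def resolve_windows(
    design: StudyDesign, span_start: pd.Timestamp, span_end: pd.Timestamp
) -> dict[str, list[Window]]:
    """Concrete per-day windows inside a trace span.

    For each calendar day the design's clock windows are anchored to that
    day (the night window ends the next morning) and kept only if fully
    contained in ``[span_start, span_end]``.  Windows are endpoint-inclusive
    on the sampling grid: a sample at exactly the window end belongs to it.
    """
    span_start, span_end = pd.Timestamp(span_start), pd.Timestamp(span_end)
    if span_end <= span_start:
        raise ValueError("empty trace span")
    out: dict[str, list[Window]] = {"night": [], "day": [], "postprandial": []}
    clock = {
        "night": design.night_window,
        "day": design.day_window,
        "postprandial": design.postprandial_window,
    }
    day0 = span_start.normalize()
    n_days = int((span_end.normalize() - day0).days) + 1
    for k in range(n_days):
        anchor: date = (day0 + timedelta(days=k)).date()
        for name, (t0, t1) in clock.items():
            w_start = pd.Timestamp(datetime.combine(anchor, t0))
            end_day = anchor if t1 > t0 else anchor + timedelta(days=1)
            w_end = pd.Timestamp(datetime.combine(end_day, t1))
            if w_start >= span_start and w_end <= span_end:
                out[name].append((w_start, w_end))
    return out
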