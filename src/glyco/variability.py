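"""Classical glycemic-variability metrics: MAGE, CONGA and time-in-range.

Conventions pinned by this package (the literature varies):

* MAGE turning points are found on the unsmoothed repaired trace by sign
  changes of the first differences; plateaus contribute their first index;
  the first and last samples count as extrema.  An amplitude between two
  consecutive alternating extrema qualifies when it exceeds one sample
  standard deviation (denominator ``n-1``) of the whole window.  Both
  directional means and their pooled mean are reported.
* CONGA(n) is the sample SD of ``g(t) - g(t - n hours)`` over every ``t``
  where both samples exist and are observed.
* Time-in-range classifies each observed sample as below (``g < lo``),
  within (``lo <= g < hi``) or above (``g >= hi``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import GlucoseTrace

__all__ = [
    "MageResult",
    "TimeInRange",
    "VariabilityMetrics",
    "turning_points",
    "compute_mage",
    "compute_conga",
    "compute_time_in_range",
    "compute_variability",
]


@dataclass(frozen=True)
class MageResult:
    """Mean amplitude of glycemic excursions, split by direction.

    ``mage`` is NaN when no excursion exceeds the 1-SD threshold (undefined,
    deliberately distinct from 0).
    """

    mage: float
    mage_up: float
    mage_down: float
    n_qualifying: int
    threshold_sd: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.mage)


@dataclass(frozen=True)
class TimeInRange:
    below: float
    within: float
    above: float

    def __post_init__(self):
        total = self.below + self.within + self.above
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"TIR fractions sum to {total}, not 1")


@dataclass(frozen=True)
class VariabilityMetrics:
    """Bundle of variability metrics for one trace or window."""

    mage: MageResult
    conga: dict[int, float] = field(default_factory=dict)
    tir: TimeInRange | None = None


def turning_points(values: np.ndarray) -> np.ndarray:
    """Indices of alternating local extrema, endpoints included.

    Plateaus (runs of equal values) are represented by their first index.
    Returns an empty array for constant input.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        return np.empty(0, dtype=int)
    # Compress plateaus, keeping the first index of each run.
    keep = np.flatnonzero(np.r_[True, np.diff(values) != 0])
    comp = values[keep]
    if len(comp) < 2:
        return np.empty(0, dtype=int)
    signs = np.sign(np.diff(comp))
    interior = np.flatnonzero(signs[1:] != signs[:-1]) + 1
    idx = np.r_[0, interior, len(comp) - 1]
    return keep[idx]


def compute_mage(trace: GlucoseTrace) -> MageResult:
    """MAGE of the observed samples of a trace.

    The qualifying threshold is one sample SD of the whole window; ascending
    and descending qualifying amplitudes are averaged separately
    (``mage_up`` / ``mage_down``) and pooled (``mage``).
    """
    values = trace.glucose[~trace.missing]
    if len(values) < 3:
        return MageResult(math.nan, math.nan, math.nan, 0, math.nan)
    sd = float(np.std(values, ddof=1))
    tp = turning_points(values)
    if len(tp) < 2 or sd == 0.0:
        return MageResult(math.nan, math.nan, math.nan, 0, sd)
    deltas = np.diff(values[tp])
    qualifying = deltas[np.abs(deltas) > sd]
    if qualifying.size == 0:
        return MageResult(math.nan, math.nan, math.nan, 0, sd)
    ups = qualifying[qualifying > 0]
    downs = -qualifying[qualifying < 0]
    return MageResult(
        mage=float(np.mean(np.abs(qualifying))),
        mage_up=float(np.mean(ups)) if ups.size else math.nan,
        mage_down=float(np.mean(downs)) if downs.size else math.nan,
        n_qualifying=int(qualifying.size),
        threshold_sd=sd,
    )


def compute_conga(trace: GlucoseTrace, n_hours: float) -> float:
    """CONGA(n): sample SD of differences between samples ``n_hours`` apart.

    Requires a uniform grid; the n-hour offset must be a whole number of
    grid steps and shorter than the trace.
    """
    minutes = trace.minutes
    if len(minutes) < 3:
        raise ValueError("trace too short for CONGA")
    steps = np.diff(minutes)
    dt = steps[0]
    if not np.allclose(steps, dt):
        raise ValueError("CONGA requires a uniform sampling grid")
    offset_min = n_hours * 60.0
    k = offset_min / dt
    if abs(k - round(k)) > 1e-9:
        raise ValueError(
            f"offset of {n_hours} h is not a whole number of {dt}-min grid steps"
        )
    k = int(round(k))
    if k < 1 or k >= len(minutes):
        raise ValueError(f"trace shorter than the {n_hours}-h CONGA offset")
    observed = ~trace.missing
    valid = observed[k:] & observed[:-k]
    diffs = trace.glucose[k:][valid] - trace.glucose[:-k][valid]
    if len(diffs) < 2:
        raise ValueError("fewer than 2 valid difference pairs for CONGA")
    return float(np.std(diffs, ddof=1))


def compute_time_in_range(
    trace: GlucoseTrace, lo: float = 70.0, hi: float = 180.0
) -> TimeInRange:
    """Fractions of observed samples below / within / at-or-above a range.

    Boundary convention: hypoglycemia is ``g < lo``, hyperglycemia ``g >= hi``.
    """
    if lo >= hi:
        raise ValueError(f"range must satisfy lo < hi, got ({lo}, {hi})")
    values = trace.glucose[~trace.missing]
    n = len(values)
    if n == 0:
        raise ValueError("no observed samples")
    below = int((values < lo).sum())
    above = int((values >= hi).sum())
    return TimeInRange(below / n, (n - below - above) / n, above / n)


def compute_variability(
    trace: GlucoseTrace,
    conga_hours: tuple[float, ...] = (1, 2, 6),
    euglycemic_range: tuple[float, float] = (70.0, 180.0),
) -> VariabilityMetrics:
    """Convenience bundle: MAGE, CONGA at several horizons and TIR."""
    conga = {}
    for h in conga_hours:
        try:
            conga[h] = compute_conga(trace, h)
        except ValueError:
            conga[h] = math.nan
    return VariabilityMetrics(
        mage=compute_mage(trace),
        conga=conga,
        tir=compute_time_in_range(trace, *euglycemic_range),
    )
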