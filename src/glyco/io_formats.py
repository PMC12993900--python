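"""Reading and writing CGM traces, blood-sample tables and study designs.

The canonical CGM CSV dialect used by this package is comma-separated with
header ``timestamp,glucose_mg_dl``, ISO-8601 timestamps and the literal
string ``NaN`` for readings the receiver flagged as off-scale.  The reader
is permissive about timestamp formats (anything :func:`pandas.to_datetime`
accepts) and can convert mmol/L input at the boundary; everything past the
reader works in mg/dL on absolute timestamps.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GlucoseTrace",
    "BloodSampleSeries",
    "StudyDesign",
    "TraceFormatError",
    "ValidationError",
    "MMOL_TO_MGDL",
    "read_cgm_csv",
    "write_cgm_csv",
    "read_blood_samples",
    "write_blood_samples",
    "load_study_design",
    "default_study_design",
]

#: Conversion factor from mmol/L to mg/dL for glucose.
MMOL_TO_MGDL = 18.016

_TRACE_SOURCES = frozenset({"raw", "repaired", "smoothed", "shifted", "simulated"})

CGM_HEADER = ("timestamp", "glucose_mg_dl")


class TraceFormatError(ValueError):
    """Raised when a CGM CSV file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when parsed data violate a domain invariant."""


@dataclass(frozen=True)
class GlucoseTrace:
    """A uniformly sampled glucose series for one animal.

    Parameters
    ----------
    animal_id :
        Identifier of the animal the trace belongs to.
    times :
        Strictly increasing absolute timestamps (nominal 5-min spacing for
        raw device data, 1-min after resampling).
    glucose :
        Glucose concentration in mg/dL per timestamp; NaN where ``missing``.
    missing :
        Boolean flag per timestamp marking off-scale / absent readings.
    source :
        Provenance tag, one of ``raw``, ``repaired``, ``smoothed``,
        ``shifted``, ``simulated``.
    """

    animal_id: str
    times: pd.DatetimeIndex
    glucose: np.ndarray
    missing: np.ndarray
    source: str = "raw"

    def __post_init__(self) -> None:
        times = pd.DatetimeIndex(self.times)
        glucose = np.asarray(self.glucose, dtype=float)
        missing = np.asarray(self.missing, dtype=bool)
        if not (len(times) == len(glucose) == len(missing)):
            raise ValidationError(
                f"length mismatch: {len(times)} times, {len(glucose)} glucose, "
                f"{len(missing)} missing flags"
            )
        if len(times) > 1 and not times.is_monotonic_increasing:
            raise ValidationError("timestamps must be increasing")
        if times.has_duplicates:
            raise ValidationError("duplicate timestamps in trace")
        observed = ~missing
        if not np.all(np.isfinite(glucose[observed])):
            raise ValidationError("non-finite glucose at a non-missing sample")
        if self.source not in _TRACE_SOURCES:
            raise ValidationError(f"unknown trace source {self.source!r}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "glucose", glucose)
        object.__setattr__(self, "missing", missing)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def minutes(self) -> np.ndarray:
        """Sample times as float minutes since the first sample."""
        if len(self.times) == 0:
            return np.empty(0)
        delta = self.times - self.times[0]
        return delta.total_seconds().to_numpy() / 60.0

    @property
    def n_observed(self) -> int:
        return int((~self.missing).sum())

    def replace(self, **changes) -> "GlucoseTrace":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def window(self, start: pd.Timestamp, end: pd.Timestamp) -> "GlucoseTrace":
        """Sub-trace of samples with ``start <= t <= end`` (endpoint inclusive)."""
        mask = (self.times >= start) & (self.times <= end)
        return self.replace(
            times=self.times[mask], glucose=self.glucose[mask], missing=self.missing[mask]
        )

    @classmethod
    def from_values(
        cls,
        values,
        start: str | pd.Timestamp = "2024-01-01 00:00",
        step_min: float = 5.0,
        animal_id: str = "pig",
        source: str = "raw",
    ) -> "GlucoseTrace":
        """Build a trace from a value list on a uniform grid (NaN = missing)."""
        values = np.asarray(values, dtype=float)
        times = pd.Timestamp(start) + pd.to_timedelta(
            np.arange(len(values)) * step_min, unit="min"
        )
        return cls(
            animal_id=animal_id,
            times=pd.DatetimeIndex(times),
            glucose=values,
            missing=np.isnan(values),
            source=source,
        )


@dataclass(frozen=True)
class BloodSampleSeries:
    """Sparse catheter plasma-glucose samples for one animal."""

    animal_id: str
    times: pd.DatetimeIndex
    plasma_glucose: np.ndarray
    hematocrit: float
    medium: str = "plasma"

    def __post_init__(self) -> None:
        times = pd.DatetimeIndex(self.times)
        glucose = np.asarray(self.plasma_glucose, dtype=float)
        if len(times) != len(glucose):
            raise ValidationError("times and plasma_glucose lengths differ")
        if len(times) > 1 and not times.is_monotonic_increasing:
            raise ValidationError("blood sample timestamps must be increasing")
        if times.has_duplicates:
            raise ValidationError("duplicate blood sample timestamps")
        if np.any(glucose <= 0):
            raise ValidationError("plasma glucose must be positive")
        if not 0.0 < self.hematocrit < 1.0:
            raise ValidationError(f"hematocrit {self.hematocrit} outside (0, 1)")
        if not 0.15 < self.hematocrit < 0.60:
            raise ValidationError(
                f"hematocrit {self.hematocrit} outside physiological range (0.15, 0.60)"
            )
        if self.medium not in ("plasma", "blood_equivalent"):
            raise ValidationError(f"unknown medium {self.medium!r}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "plasma_glucose", glucose)

    def __len__(self) -> int:
        return len(self.times)


def _parse_clock(value) -> time:
    if isinstance(value, time):
        return value
    if isinstance(value, int):  # YAML reads unquoted HH:MM as sexagesimal minutes
        return time(value // 60, value % 60)
    hh, mm = str(value).split(":")
    return time(int(hh), int(mm))


@dataclass(frozen=True)
class StudyDesign:
    """Clock-time windows and feeding layout of a monitoring study.

    Windows are (start, end) wall-clock pairs, endpoint inclusive on the
    sampling grid; the night window may wrap past midnight.
    """

    night_window: tuple[time, time] = (time(21, 0), time(6, 55))
    day_window: tuple[time, time] = (time(7, 0), time(20, 55))
    postprandial_window: tuple[time, time] = (time(8, 45), time(13, 0))
    meal_times: tuple[time, ...] = (time(9, 0), time(16, 0))
    diet_sequence: tuple[tuple[int, str, float], ...] = (
        (1, "HS", 1.0),
        (2, "HS", 1.0),
        (3, "HS75/HF25", 0.75),
        (4, "HS50/HF50", 0.5),
        (5, "HF", 0.0),
    )
    euglycemic_range: tuple[float, float] = (70.0, 180.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "night_window", tuple(map(_parse_clock, self.night_window)))
        object.__setattr__(self, "day_window", tuple(map(_parse_clock, self.day_window)))
        object.__setattr__(
            self, "postprandial_window", tuple(map(_parse_clock, self.postprandial_window))
        )
        object.__setattr__(self, "meal_times", tuple(map(_parse_clock, self.meal_times)))
        lo, hi = self.euglycemic_range
        if not lo < hi:
            raise ValidationError("euglycemic range must satisfy lo < hi")
        # Night wraps midnight; day must not intrude into it.
        day_start, day_end = self.day_window
        night_start, night_end = self.night_window
        if day_start <= night_end or day_end >= night_start:
            raise ValidationError("day window overlaps night window")


def read_cgm_csv(
    path, animal_id: str | None = None, unit: str = "mg_dl"
) -> GlucoseTrace:
    """Read a CGM trace from the canonical CSV dialect.

    Rows whose glucose field is the literal ``NaN`` (any case) or empty are
    flagged missing.  Rows are sorted by timestamp; duplicate timestamps and
    unparseable fields raise :class:`TraceFormatError` naming the row.

    Parameters
    ----------
    path :
        CSV file with columns ``timestamp`` and ``glucose_mg_dl`` (or
        ``glucose_mmol_l`` with ``unit='mmol_l'``).
    animal_id :
        Identifier to attach; defaults to the file stem.
    unit :
        ``'mg_dl'`` (default) or ``'mmol_l'`` to convert on read.
    """
    path = Path(path)
    if animal_id is None:
        animal_id = path.stem
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise TraceFormatError(f"{path}: empty file") from None
    glucose_col = "glucose_mg_dl" if unit == "mg_dl" else "glucose_mmol_l"
    for col in ("timestamp", glucose_col):
        if col not in frame.columns:
            raise TraceFormatError(f"{path}: missing required column {col!r}")

    times = pd.to_datetime(frame["timestamp"], errors="coerce", format="mixed")
    bad = times.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise TraceFormatError(
            f"{path}: unparseable timestamp {frame['timestamp'].iloc[row]!r} at data row {row}"
        )
    raw = frame[glucose_col].str.strip()
    missing = raw.str.lower().isin({"nan", "na", ""}).to_numpy()
    glucose = np.full(len(raw), np.nan)
    for row, (text, miss) in enumerate(zip(raw, missing)):
        if miss:
            continue
        try:
            # float() is the exact shortest-roundtrip parser (pd.to_numeric is not)
            glucose[row] = float(text)
        except ValueError:
            raise TraceFormatError(
                f"{path}: unparseable glucose {text!r} at data row {row}"
            ) from None
        if not np.isfinite(glucose[row]):
            raise TraceFormatError(
                f"{path}: non-finite glucose {text!r} at data row {row}"
            )
    if times.duplicated().any():
        dup = times[times.duplicated()].iloc[0]
        raise TraceFormatError(f"{path}: duplicate timestamp {dup}")
    if unit == "mmol_l":
        glucose = glucose * MMOL_TO_MGDL
    elif unit != "mg_dl":
        raise ValueError(f"unknown unit {unit!r}")

    order = np.argsort(times.to_numpy(), kind="stable")
    return GlucoseTrace(
        animal_id=animal_id,
        times=pd.DatetimeIndex(times.to_numpy()[order]),
        glucose=glucose[order],
        missing=missing[order],
        source="raw",
    )


def write_cgm_csv(trace: GlucoseTrace, path) -> Path:
    """Write a trace in the canonical dialect; missing points become ``NaN``.

    Values are serialized with Python's shortest-roundtrip float repr, so
    :func:`read_cgm_csv` inverts this bit-exactly.
    """
    path = Path(path)
    lines = [",".join(CGM_HEADER)]
    stamps = trace.times.strftime("%Y-%m-%dT%H:%M:%S")
    for stamp, value, miss in zip(stamps, trace.glucose, trace.missing):
        lines.append(f"{stamp},{'NaN' if miss else repr(float(value))}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_blood_samples(path, animal_id: str | None = None) -> BloodSampleSeries:
    """Read a sparse blood-sample table.

    Expected columns: ``animal_id,time,plasma_glucose,hematocrit``.  If the
    table holds several animals, ``animal_id`` selects one; otherwise the
    table must contain exactly one.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise TraceFormatError(f"{path}: empty file") from None
    required = {"animal_id", "time", "plasma_glucose", "hematocrit"}
    missing_cols = required - set(frame.columns)
    if missing_cols:
        raise TraceFormatError(f"{path}: missing columns {sorted(missing_cols)}")
    frame["animal_id"] = frame["animal_id"].astype(str)
    if animal_id is not None:
        frame = frame[frame["animal_id"] == str(animal_id)]
        if frame.empty:
            raise ValidationError(f"{path}: no rows for animal {animal_id!r}")
    else:
        ids = frame["animal_id"].unique()
        if len(ids) != 1:
            raise ValidationError(
                f"{path}: {len(ids)} animals present; pass animal_id to select one"
            )
        animal_id = ids[0]
    times = pd.to_datetime(frame["time"], errors="coerce", format="mixed")
    if times.isna().any():
        row = int(np.flatnonzero(times.isna().to_numpy())[0])
        raise TraceFormatError(f"{path}: unparseable time at data row {row}")
    hct = frame["hematocrit"].astype(float).to_numpy()
    if not np.allclose(hct, hct[0]):
        raise ValidationError(f"{path}: hematocrit differs across rows for one animal")
    order = np.argsort(times.to_numpy(), kind="stable")
    return BloodSampleSeries(
        animal_id=str(animal_id),
        times=pd.DatetimeIndex(times.to_numpy()[order]),
        plasma_glucose=frame["plasma_glucose"].astype(float).to_numpy()[order],
        hematocrit=float(hct[0]),
    )


def write_blood_samples(series: BloodSampleSeries, path) -> Path:
    """Write a blood-sample series as a CSV table."""
    path = Path(path)
    frame = pd.DataFrame(
        {
            "animal_id": series.animal_id,
            "time": series.times.strftime("%Y-%m-%dT%H:%M:%S"),
            "plasma_glucose": series.plasma_glucose,
            "hematocrit": series.hematocrit,
        }
    )
    frame.to_csv(path, index=False)
    return path


def default_study_design() -> StudyDesign:
    """The package's default windows: night 21:00-06:55, day 07:00-20:55,
    postprandial 08:45-13:00, euglycemic range 70-180 mg/dL."""
    return StudyDesign()


def load_study_design(path) -> StudyDesign:
    """Load a :class:`StudyDesign` from a YAML file.

    Recognized keys: ``night_window``, ``day_window``, ``postprandial_window``
    (each ``[HH:MM, HH:MM]``), ``meal_times`` (list of ``HH:MM``),
    ``diet_sequence`` (list of ``[day, label, hs_fraction]``) and
    ``euglycemic_range`` (``[lo, hi]``).  Missing keys fall back to defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for key in ("night_window", "day_window", "postprandial_window"):
        if key in raw:
            kwargs[key] = tuple(raw[key])
    if "meal_times" in raw:
        kwargs["meal_times"] = tuple(raw["meal_times"])
    if "diet_sequence" in raw:
        kwargs["diet_sequence"] = tuple(
            (int(d), str(label), float(frac)) for d, label, frac in raw["diet_sequence"]
        )
    if "euglycemic_range" in raw:
        lo, hi = raw["euglycemic_range"]
        kwargs["euglycemic_range"] = (float(lo), float(hi))
    return StudyDesign(**kwargs)
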