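"""Synthetic cohort generator for CGM analysis testing.

Produces per-animal "true" blood-glucose traces (basal level + circadian
sinusoid + gamma-shaped meal responses + Poisson-timed nocturnal wavelets),
matching CGM traces (interstitial delay + constant bias + AR(1) sensor noise
+ injected missing points) and sparse plasma samples on the serial-sampling
schedule, together with a truth record for parameter-recovery tests.
Everything is deterministic per (seed, animal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import datetime, time, timedelta

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_formats import BloodSampleSeries, GlucoseTrace, StudyDesign, default_study_design

__all__ = [
    "MealResponse",
    "WaveletConfig",
    "SensorConfig",
    "SimConfig",
    "StudyBundle",
    "BLOOD_SCHEDULE_MIN",
    "simulate_true_blood",
    "simulate_cgm",
    "simulate_blood_samples",
    "simulate_study",
]

#: Serial blood-sampling schedule in minutes relative to the test meal:
#: one pre-meal sample at -15 min and 14 postprandial samples.
BLOOD_SCHEDULE_MIN = (-15, 10, 20, 30, 40, 50, 60, 75, 90, 105, 120, 150, 180, 210, 240)


@dataclass(frozen=True)
class MealResponse:
    """Gamma-shaped postprandial impulse response."""

    amplitude: float = 60.0  # mg/dL at the peak
    time_to_peak: tuple[float, float] = (35.0, 55.0)  # min, per-animal uniform range
    decay_halflife: float = 60.0  # min, from the peak

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class WaveletConfig:
    """Poisson-timed symmetric nocturnal glucose bumps."""

    rate_per_night: float = 2.0
    amplitude_range: tuple[float, float] = (15.0, 40.0)  # mg/dL, sign random
    duration_range: tuple[float, float] = (30.0, 60.0)  # min (full width)


@dataclass(frozen=True)
class SensorConfig:
    """CGM sensor error model."""

    bias: float = 20.0  # mg/dL constant overestimation
    noise_sd: float = 3.0  # stationary SD of the AR(1) noise
    ar1_coefficient: float = 0.7
    lag_min: float = 14.0  # interstitial delay, minutes

    def __post_init__(self):
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ValueError("ar1_coefficient must be in [0, 1)")


@dataclass(frozen=True)
class SimConfig:
    """Full cohort simulation configuration."""

    n_animals: int = 8
    days: int = 5
    sample_interval_min: float = 5.0
    start: str = "2024-03-04 00:00"
    basal_mean: float = 100.0
    basal_sd_between_animals: float = 5.0
    circadian_amplitude: float = 8.0
    circadian_acrophase_h: float = 15.0  # clock hour of the circadian maximum
    meal_times: tuple[time, ...] = (time(9, 0), time(16, 0))
    meal_response: dict[str, MealResponse] = field(
        default_factory=lambda: {
            "HS": MealResponse(amplitude=60.0, time_to_peak=(35.0, 55.0), decay_halflife=60.0),
            "HF": MealResponse(amplitude=35.0, time_to_peak=(20.0, 155.0), decay_halflife=90.0),
        }
    )
    amplitude_sd_between_animals: float = 5.0
    diet_by_day: tuple[float, ...] = (1.0, 1.0, 0.75, 0.5, 0.0)  # HS fraction per day
    meal_test_days: tuple[int, ...] = (2, 5)  # 1-based days with serial blood sampling
    wavelets: WaveletConfig = field(default_factory=WaveletConfig)
    sensor: SensorConfig = field(default_factory=SensorConfig)
    missing_rate: float = 0.01
    hematocrit_mean: float = 0.40
    hematocrit_sd: float = 0.03
    assay_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.missing_rate <= 0.2:
            raise ValueError("missing_rate must be in [0, 0.2]")
        if self.circadian_amplitude < 0:
            raise ValueError("circadian_amplitude must be >= 0")
        if len(self.diet_by_day) < self.days:
            raise ValueError("diet_by_day must cover every simulated day")


@dataclass
class StudyBundle:
    """Everything one simulated study produces."""

    config: SimConfig
    design: StudyDesign
    true_traces: dict[str, GlucoseTrace]
    cgm_traces: dict[str, GlucoseTrace]
    blood_samples: dict[tuple[str, int], BloodSampleSeries]  # (animal, test day)
    truth: dict


def _animal_rng(seed: int, animal_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, animal_index, stream]))


def _gamma_shape_exponent(time_to_peak: float, halflife: float) -> float:
    """Exponent k of the unit response (t/tp)^k * exp(k(1 - t/tp)) such that
    the decay from the peak halves after ``halflife`` minutes."""
    ratio = halflife / time_to_peak

    def residual(k):
        return k * (math.log1p(ratio) - ratio) + math.log(2.0)

    return brentq(residual, 1e-3, 1e4)


def _meal_curve(minutes: np.ndarray, onset: float, amplitude: float,
                time_to_peak: float, halflife: float) -> np.ndarray:
    """Gamma-shaped response peaking at ``amplitude`` exactly ``time_to_peak``
    minutes after ``onset``; zero before onset."""
    k = _gamma_shape_exponent(time_to_peak, halflife)
    t = np.maximum(minutes - onset, 0.0) / time_to_peak
    with np.errstate(divide="ignore", invalid="ignore"):
        curve = amplitude * np.where(t > 0, np.exp(k * (np.log(np.where(t > 0, t, 1.0)) + 1.0 - t)), 0.0)
    return curve


def _blend_meal(cfg: SimConfig, hs_fraction: float) -> MealResponse:
    hs, hf = cfg.meal_response["HS"], cfg.meal_response["HF"]
    w = float(hs_fraction)
    return MealResponse(
        amplitude=w * hs.amplitude + (1 - w) * hf.amplitude,
        time_to_peak=(
            w * hs.time_to_peak[0] + (1 - w) * hf.time_to_peak[0],
            w * hs.time_to_peak[1] + (1 - w) * hf.time_to_peak[1],
        ),
        decay_halflife=w * hs.decay_halflife + (1 - w) * hf.decay_halflife,
    )


def _night_intervals(cfg: SimConfig, design: StudyDesign, total_min: float):
    """(start_min, end_min) of every night window inside the simulated span."""
    start_ts = pd.Timestamp(cfg.start)
    t0, t1 = design.night_window
    out = []
    for day in range(cfg.days + 1):
        anchor = (start_ts.normalize() + pd.Timedelta(days=day)).date()
        w0 = pd.Timestamp(datetime.combine(anchor, t0))
        w1 = pd.Timestamp(datetime.combine(anchor + timedelta(days=1), t1))
        m0 = (w0 - start_ts).total_seconds() / 60.0
        m1 = (w1 - start_ts).total_seconds() / 60.0
        if m0 >= 0 and m1 <= total_min:
            out.append((m0, m1))
    return out


def simulate_true_blood(
    config: SimConfig,
    animal_index: int = 0,
    seed: int | None = None,
    design: StudyDesign | None = None,
    return_truth: bool = False,
):
    """Simulate one animal's true blood-glucose trace on the 5-min grid.

    The trace is basal level + circadian sinusoid + per-meal gamma responses
    + nocturnal wavelets; deterministic for a given (seed, animal_index).
    With ``return_truth=True`` also returns the injected-event record.
    """
    seed = config.seed if seed is None else seed
    design = design or default_study_design()
    rng = _animal_rng(seed, animal_index, stream=0)
    n = int(round(config.days * 24 * 60 / config.sample_interval_min))
    minutes = np.arange(n) * config.sample_interval_min
    start_ts = pd.Timestamp(config.start)

    basal = config.basal_mean + rng.normal(0.0, config.basal_sd_between_animals)
    clock_h = (start_ts.hour + start_ts.minute / 60.0 + minutes / 60.0) % 24
    glucose = basal + config.circadian_amplitude * np.cos(
        2 * np.pi * (clock_h - config.circadian_acrophase_h) / 24.0
    )

    amp_jitter = rng.normal(0.0, config.amplitude_sd_between_animals)
    meals = []
    for day in range(config.days):
        resp = _blend_meal(config, config.diet_by_day[day])
        for meal_clock in config.meal_times:
            onset = day * 24 * 60 + meal_clock.hour * 60 + meal_clock.minute - (
                start_ts.hour * 60 + start_ts.minute
            )
            if onset < 0 or onset > minutes[-1]:
                continue
            tp = rng.uniform(*resp.time_to_peak)
            amplitude = max(resp.amplitude + amp_jitter, 0.0)
            glucose += _meal_curve(minutes, onset, amplitude, tp, resp.decay_halflife)
            meals.append(
                {"day": day + 1, "onset_min": float(onset), "amplitude": float(amplitude),
                 "time_to_peak": float(tp), "halflife": float(resp.decay_halflife)}
            )

    wavelets = []
    wl = config.wavelets
    for night_idx, (m0, m1) in enumerate(_night_intervals(config, design, minutes[-1])):
        count = rng.poisson(wl.rate_per_night)
        for _ in range(count):
            center = rng.uniform(m0, m1)
            amplitude = rng.uniform(*wl.amplitude_range)
            duration = rng.uniform(*wl.duration_range)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            sigma = duration / 4.0  # ~95 % of the bump inside `duration`
            glucose += sign * amplitude * np.exp(-0.5 * ((minutes - center) / sigma) ** 2)
            wavelets.append(
                {"night": night_idx + 1, "center_min": float(center),
                 "amplitude": float(amplitude), "duration": float(duration),
                 "sign": int(sign)}
            )

    if np.any(glucose <= 0):
        raise ValueError("configuration produced non-positive glucose")
    trace = GlucoseTrace(
        animal_id=f"pig{animal_index + 1:02d}",
        times=pd.DatetimeIndex(start_ts + pd.to_timedelta(minutes, unit="min")),
        glucose=glucose,
        missing=np.zeros(n, dtype=bool),
        source="simulated",
    )
    if return_truth:
        return trace, {"basal": float(basal), "meals": meals, "wavelets": wavelets}
    return trace


def simulate_cgm(
    true_blood: GlucoseTrace, config: SimConfig, seed: int | None = None,
    animal_index: int = 0,
) -> GlucoseTrace:
    """Derive the CGM reading from a true blood trace.

    CGM = blood delayed by the sensor lag, plus constant bias, plus
    stationary AR(1) noise; missing points are then injected at
    ``missing_rate`` (never the first or last sample).
    """
    seed = config.seed if seed is None else seed
    rng = _animal_rng(seed, animal_index, stream=1)
    sensor = config.sensor
    minutes = true_blood.minutes
    if sensor.lag_min != 0:
        from scipy.interpolate import CubicSpline

        spline = CubicSpline(minutes, true_blood.glucose)
        shifted = np.clip(minutes - sensor.lag_min, minutes[0], minutes[-1])
        delayed = spline(shifted)
    else:
        delayed = true_blood.glucose.copy()
    n = len(delayed)
    noise = np.zeros(n)
    if sensor.noise_sd > 0:
        phi = sensor.ar1_coefficient
        innovations = rng.normal(0.0, sensor.noise_sd * math.sqrt(1 - phi**2), size=n)
        noise[0] = rng.normal(0.0, sensor.noise_sd)
        for i in range(1, n):
            noise[i] = phi * noise[i - 1] + innovations[i]
    glucose = delayed + sensor.bias + noise
    missing = np.zeros(n, dtype=bool)
    if config.missing_rate > 0 and n > 2:
        missing[1:-1] = rng.random(n - 2) < config.missing_rate
    glucose = np.where(missing, np.nan, glucose)
    return true_blood.replace(glucose=glucose, missing=missing, source="simulated")


def simulate_blood_samples(
    true_blood: GlucoseTrace,
    meal_time: pd.Timestamp,
    hematocrit: float,
    seed: int | None = None,
    schedule_min: tuple[float, ...] = BLOOD_SCHEDULE_MIN,
    assay_noise_sd: float = 2.0,
    animal_index: int = 0,
) -> BloodSampleSeries:
    """Sparse plasma samples on the serial-sampling schedule around a meal.

    Plasma = true blood / (1 - hematocrit) + assay noise, so hematocrit
    conversion recovers true blood exactly at zero noise.
    """
    seed = 0 if seed is None else seed
    meal_time = pd.Timestamp(meal_time)
    offsets = np.asarray(schedule_min, dtype=float)
    meal_offset = (meal_time - true_blood.times[0]).total_seconds() / 60.0
    # Fold the meal position in so repeated test days get fresh assay noise.
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, animal_index, 2, int(round(meal_offset))])
    )
    sample_min = meal_offset + offsets
    minutes = true_blood.minutes
    if sample_min.min() < minutes[0] or sample_min.max() > minutes[-1]:
        raise ValueError("sampling schedule falls outside the trace span")
    blood = np.interp(sample_min, minutes, true_blood.glucose)
    plasma = blood / (1.0 - hematocrit)
    if assay_noise_sd > 0:
        plasma = plasma + rng.normal(0.0, assay_noise_sd, size=len(plasma))
    return BloodSampleSeries(
        animal_id=true_blood.animal_id,
        times=pd.DatetimeIndex(true_blood.times[0] + pd.to_timedelta(sample_min, unit="min")),
        plasma_glucose=plasma,
        hematocrit=hematocrit,
    )


def simulate_study(config: SimConfig, design: StudyDesign | None = None) -> StudyBundle:
    """Simulate a full cohort: true traces, CGM traces, serial blood samples
    on the meal-test days, and a truth record for recovery tests."""
    design = design or default_study_design()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 10_000]))
    hematocrits = np.clip(
        rng.normal(config.hematocrit_mean, config.hematocrit_sd, size=config.n_animals),
        0.2, 0.55,
    )
    true_traces: dict[str, GlucoseTrace] = {}
    cgm_traces: dict[str, GlucoseTrace] = {}
    blood: dict[tuple[str, int], BloodSampleSeries] = {}
    truth: dict = {
        "seed": config.seed,
        "sensor": asdict(config.sensor),
        "animals": {},
    }
    start_ts = pd.Timestamp(config.start)
    morning = config.meal_times[0]
    for i in range(config.n_animals):
        true, animal_truth = simulate_true_blood(
            config, animal_index=i, design=design, return_truth=True
        )
        cgm = simulate_cgm(true, config, animal_index=i)
        true_traces[true.animal_id] = true
        cgm_traces[cgm.animal_id] = cgm
        animal_truth["hematocrit"] = float(hematocrits[i])
        animal_truth["lag_min"] = config.sensor.lag_min
        animal_truth["bias"] = config.sensor.bias
        for day in config.meal_test_days:
            if day > config.days:
                continue
            meal_ts = pd.Timestamp(
                datetime.combine(
                    (start_ts.normalize() + pd.Timedelta(days=day - 1)).date(), morning
                )
            )
            blood[(true.animal_id, day)] = simulate_blood_samples(
                true,
                meal_time=meal_ts,
                hematocrit=float(hematocrits[i]),
                seed=config.seed,
                assay_noise_sd=config.assay_noise_sd,
                animal_index=i,
            )
        truth["animals"][true.animal_id] = animal_truth
    return StudyBundle(
        config=config,
        design=design,
        true_traces=true_traces,
        cgm_traces=cgm_traces,
        blood_samples=blood,
        truth=truth,
    )
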