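"""End-to-end study analysis: per-animal preprocessing, window metrics,
sensor-blood agreement, and cohort statistics, with a traceable run log.

Exit-code contract: 0 all animals analysed, 1 some failed, 2 all failed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import bland_altman, convert_series_to_blood, estimate_lag, pair_on_grid
from .excursions import compute_baseline, detect_excursions, resolve_windows, summarize_period
from .io_formats import (
    BloodSampleSeries,
    GlucoseTrace,
    StudyDesign,
    default_study_design,
    load_study_design,
    read_blood_samples,
    read_cgm_csv,
)
from .preprocess import repair_missing, resample_minutely, smooth_savgol
from .stats import diet_anova, pca_metrics, spearman_screen, variance_f_test
from .synthetic import SimConfig, simulate_study
from .variability import compute_variability

logger = logging.getLogger("glyco")

DEFAULT_CONFIG = {
    "preprocess": {"window": 9, "order": 3},
    "baseline": {"reference": "preceding_night", "min_samples": 10},
    "align": {"max_lag": 60},
    "variability": {"conga_hours": [1, 2, 6]},
    "seed": 0,
}

EXIT_OK, EXIT_PARTIAL, EXIT_TOTAL_FAILURE = 0, 1, 2


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, raw)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def analyze_animal(
    cgm: GlucoseTrace,
    design: StudyDesign,
    config: dict,
    blood: dict[int, BloodSampleSeries] | None = None,
    diet_label: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyse one animal; returns (tidy metric rows, agreement rows)."""
    pp = config["preprocess"]
    repaired = repair_missing(cgm)
    smoothed = smooth_savgol(repaired, window=pp["window"], order=pp["order"])
    windows = resolve_windows(design, smoothed.times[0], smoothed.times[-1])

    metric_rows = []
    nights = windows["night"]
    for period in ("night", "day", "postprandial"):
        for w_start, w_end in windows[period]:
            if period == "night":
                ref = (w_start, w_end)
            else:
                prior = [nw for nw in nights if nw[1] <= w_start]
                if not prior:
                    logger.warning(
                        "%s: no preceding night for %s window starting %s; skipped",
                        cgm.animal_id, period, w_start,
                    )
                    continue
                ref = prior[-1]
            try:
                band = compute_baseline(
                    smoothed, ref, min_samples=config["baseline"]["min_samples"]
                )
            except ValueError as exc:
                logger.warning("%s: baseline failed for %s: %s", cgm.animal_id, period, exc)
                continue
            excursions = detect_excursions(smoothed, band, (w_start, w_end))
            summary = summarize_period(excursions, smoothed, band, (w_start, w_end), period)
            var = compute_variability(
                smoothed.window(w_start, w_end),
                conga_hours=tuple(config["variability"]["conga_hours"]),
                euglycemic_range=design.euglycemic_range,
            )
            row = {
                "animal_id": cgm.animal_id,
                "diet": diet_label or "",
                "period": period,
                "window_start": w_start,
                "window_end": w_end,
                "baseline_mean": band.mean,
                "baseline_sd": band.sd,
                **summary.as_dict(),
                "mage": var.mage.mage,
                "tir_below": var.tir.below,
                "tir_within": var.tir.within,
                "tir_above": var.tir.above,
            }
            for h, value in var.conga.items():
                row[f"conga_{h}h"] = value
            metric_rows.append(row)

    agreement_rows = []
    if blood:
        cgm_1min = resample_minutely(smoothed)
        for day, series in sorted(blood.items()):
            try:
                agreement_rows.append(
                    _agreement_for_test_day(cgm_1min, series, day, config)
                )
            except ValueError as exc:
                logger.warning(
                    "%s day %s: agreement analysis failed: %s", cgm.animal_id, day, exc
                )
    return pd.DataFrame(metric_rows), pd.DataFrame(agreement_rows)


def _agreement_for_test_day(
    cgm_1min: GlucoseTrace, series: BloodSampleSeries, day: int, config: dict
) -> dict:
    """Lag estimation + hematocrit conversion + Bland-Altman for one test day."""
    blood_eq = convert_series_to_blood(series)
    # Dense blood curve via spline over the sparse samples, for cross-correlation.
    sparse = GlucoseTrace(
        animal_id=series.animal_id,
        times=blood_eq.times,
        glucose=blood_eq.plasma_glucose,
        missing=np.zeros(len(blood_eq), dtype=bool),
        source="repaired",
    )
    blood_1min = resample_minutely(sparse)
    max_lag = int(config["align"]["max_lag"])
    span = (blood_1min.times[-1] - blood_1min.times[0]).total_seconds() / 60.0
    max_lag = min(max_lag, int(span // 4))
    result = estimate_lag(cgm_1min, blood_1min, max_lag=max_lag)
    cgm_vals, blood_vals = pair_on_grid(
        result.shifted_trace, blood_eq.times, blood_eq.plasma_glucose
    )
    ba = bland_altman(cgm_vals, blood_vals)
    return {
        "animal_id": series.animal_id,
        "test_day": day,
        "lag_min": result.lag,
        "peak_correlation": result.peak_correlation,
        "bias": ba.bias,
        "loa_lower": ba.loa_lower,
        "loa_upper": ba.loa_upper,
        "n_pairs": ba.n_pairs,
    }


def cohort_statistics(metrics: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Cohort-level tables: night/day ANOVA + F-tests, night-post Spearman
    screen, PCA explained variance.  Sections that lack data are omitted."""
    out: dict[str, pd.DataFrame] = {}
    value_cols = [
        c for c in metrics.columns
        if metrics[c].dtype.kind in "if" and c not in ("window_start", "window_end")
    ]

    night = metrics[metrics["period"] == "night"]
    day = metrics[metrics["period"] == "day"]
    if len(night) >= 2 and len(day) >= 2:
        rows = []
        for col in value_cols:
            a = night[col].dropna().to_numpy()
            b = day[col].dropna().to_numpy()
            if len(a) < 2 or len(b) < 2:
                continue
            try:
                f_anova, p_anova = diet_anova(
                    np.concatenate([a, b]), np.array(["night"] * len(a) + ["day"] * len(b))
                )
                f_var, p_var = variance_f_test(a, b)
            except ValueError:
                continue
            rows.append(
                {"metric": col, "anova_F": f_anova, "anova_p": p_anova,
                 "var_F": f_var, "var_p": p_var}
            )
        if rows:
            out["night_vs_day"] = pd.DataFrame(rows)

    post = metrics[metrics["period"] == "postprandial"]
    if len(post) >= 4 and len(night) >= 4:
        night_first = night.groupby("animal_id", as_index=False)[value_cols].first()
        post_first = post.groupby("animal_id", as_index=False)[value_cols].first()
        shared = set(night_first["animal_id"]) & set(post_first["animal_id"])
        if len(shared) >= 4:
            screen_cols = [
                "animal_id", "n_peaks", "n_nadirs", "total_peak_duration",
                "total_nadir_duration", "total_peak_auc", "total_nadir_auc",
                "max_glucose", "min_glucose", "sharpest_peak_duration",
                "sharpest_peak_auc", "sharpest_nadir_duration", "sharpest_nadir_auc",
            ]
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                out["night_post_screen"] = spearman_screen(
                    night_first[screen_cols], post_first[screen_cols]
                )

    pca_input = metrics.groupby(["animal_id", "period"], as_index=False)[value_cols].mean()
    numeric = pca_input[value_cols].dropna(axis=1)
    numeric = numeric.loc[:, numeric.std(ddof=1) > 0]
    if numeric.shape[0] >= 3 and numeric.shape[1] >= 2:
        pca = pca_metrics(numeric)
        out["pca_explained"] = pd.DataFrame(
            {
                "component": np.arange(1, len(pca.explained_variance_ratio) + 1),
                "explained_variance_ratio": pca.explained_variance_ratio,
            }
        )
    return out


def run_pipeline(config: dict, out_dir) -> int:
    """Run the full analysis described by a config dict; write a report
    bundle (tidy CSVs + run log JSON) to ``out_dir``; return an exit code."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = _merge(DEFAULT_CONFIG, config)
    seed = int(config.get("seed", 0))

    design = default_study_design()
    cgm_traces: dict[str, GlucoseTrace] = {}
    blood: dict[str, dict[int, BloodSampleSeries]] = {}
    diets: dict[str, str] = {}
    failures: list[dict] = []

    if "simulate" in config:
        sim_kwargs = dict(config["simulate"] or {})
        sim_kwargs.setdefault("seed", seed)
        bundle = simulate_study(SimConfig(**sim_kwargs))
        design = bundle.design
        cgm_traces = bundle.cgm_traces
        for (animal, day), series in bundle.blood_samples.items():
            blood.setdefault(animal, {})[day] = series
    else:
        inputs = config.get("inputs", {})
        if "design" in inputs:
            design = load_study_design(inputs["design"])
        cgm_dir = Path(inputs.get("cgm_dir", "."))
        for path in sorted(cgm_dir.glob("*.csv")):
            if path.name.startswith("blood"):
                continue
            try:
                trace = read_cgm_csv(path)
                cgm_traces[trace.animal_id] = trace
            except Exception as exc:  # noqa: BLE001 - isolation contract
                logger.error("failed to read %s: %s", path, exc)
                failures.append({"animal_id": path.stem, "error": str(exc)})
        blood_path = inputs.get("blood")
        if blood_path:
            table = pd.read_csv(blood_path)
            for animal in table["animal_id"].astype(str).unique():
                try:
                    blood.setdefault(animal, {})[0] = read_blood_samples(
                        blood_path, animal_id=animal
                    )
                except Exception as exc:  # noqa: BLE001
                    logger.error("failed to read blood for %s: %s", animal, exc)

    if not cgm_traces:
        logger.error("no CGM traces to analyse")
        return EXIT_TOTAL_FAILURE

    all_metrics, all_agreement = [], []
    for animal_id in sorted(cgm_traces):
        try:
            metrics, agreement = analyze_animal(
                cgm_traces[animal_id],
                design,
                config,
                blood=blood.get(animal_id),
                diet_label=diets.get(animal_id),
            )
            all_metrics.append(metrics)
            if len(agreement):
                all_agreement.append(agreement)
        except Exception as exc:  # noqa: BLE001 - per-animal isolation
            logger.error("animal %s failed: %s", animal_id, exc)
            failures.append({"animal_id": animal_id, "error": str(exc)})

    n_ok = len(all_metrics)
    if n_ok:
        metrics = pd.concat(all_metrics, ignore_index=True)
        metrics.to_csv(out_dir / "period_metrics.csv", index=False)
        long = metrics.melt(
            id_vars=["animal_id", "diet", "period", "window_start", "window_end"],
            var_name="metric",
            value_name="value",
        )
        long.to_csv(out_dir / "metrics_long.csv", index=False)
        for name, table in cohort_statistics(metrics).items():
            table.to_csv(out_dir / f"{name}.csv", index=False)
    if all_agreement:
        pd.concat(all_agreement, ignore_index=True).to_csv(
            out_dir / "agreement.csv", index=False
        )

    log = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": seed,
        "n_animals": len(cgm_traces),
        "n_analyzed": n_ok,
        "failures": failures,
        "config": json.loads(json.dumps(config, default=str)),
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))

    if n_ok == 0:
        return EXIT_TOTAL_FAILURE
    if failures:
        return EXIT_PARTIAL
    return EXIT_OK
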