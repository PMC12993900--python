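# glyco

Analysis toolkit for continuous glucose monitoring (CGM) traces in animal
studies: signal repair and smoothing, glycemic-variability metrics (MAGE,
CONGA, time-in-range), baseline-band peak/nadir excursion detection with
per-period summaries, CGM-vs-blood time-shift alignment and Bland-Altman
agreement, a cohort statistics layer, and a fully deterministic synthetic
study simulator so every stage is testable without real sensor exports.

## Data formats

* **CGM trace CSV** — header `timestamp,glucose_mg_dl`, ISO-8601 timestamps,
  one reading per 5 min, literal `NaN` for off-scale readings. A permissive
  reader accepts any pandas-parseable timestamp and mmol/L input
  (`--unit mmol_l`, x 18.016 at the boundary). All internal computation is
  in mg/dL on absolute timestamps.
* **Blood sample CSV** — columns `animal_id,time,plasma_glucose,hematocrit`;
  one animal per series, hematocrit constant within a series.
* **Study design YAML** — clock windows (defaults: night 21:00-06:55, day
  07:00-20:55, postprandial 08:45-13:00, all endpoint-inclusive on the
  sampling grid), meal times, diet sequence, euglycemic range (70-180 mg/dL).

## Conventions worth knowing

* SD everywhere is the sample SD (n-1 denominator).
* The baseline band is mean +/- 1 SD over a reference window (default: the
  night preceding the analysed day); excursions are maximal runs strictly
  outside the band. Excursion AUC is the trapezoidal integral of the excess
  beyond the crossed band edge, over run samples only.
* MAGE turning points come from sign changes of first differences on the
  repaired trace (plateaus keep their first index; endpoints count);
  amplitudes qualify above 1 window-SD. If nothing qualifies, MAGE is
  reported as NaN, not 0.
* Time-in-range boundaries: hypoglycemia `g < lo`, hyperglycemia `g >= hi`.
* Lag sign: positive lag means the CGM trails blood glucose. Hematocrit
  conversion is `blood = plasma * (1 - hematocrit)` (glucose confined to the
  plasma fraction).
* The relative range (`relative_range_pct`) uses the window maximum as the
  denominator: `100 * (max - min) / max`.

## CLI

```bash
glyco simulate --seed 1 --out data/            # synthetic cohort + truth.json
glyco validate data/pig01.csv                  # dialect & invariant check
glyco convert raw.csv canonical.csv            # normalize (optionally mmol/L)
glyco preprocess data/pig01.csv out.csv --window 9 --order 3
glyco variability data/pig01.csv --conga 1 --conga 2 --conga 6 --range 70 180
glyco excursions data/pig01.csv --design design.yaml
glyco align data/pig01.csv data/blood_pig01_d2.csv --max-lag 60
glyco run --config study.yaml --out results/   # full pipeline, exit 0/1/2
```

A minimal `study.yaml` for a simulated run:

```yaml
seed: 1
simulate:
  n_animals: 8
  days: 5
```

or, for real files:

```yaml
inputs:
  cgm_dir: data/
  blood: data/blood.csv
  design: design.yaml
preprocess: {window: 9, order: 3}
align: {max_lag: 60}
```

`glyco run` writes tidy CSV reports (`period_metrics.csv`,
`metrics_long.csv`, `agreement.csv`, cohort statistics tables) plus
`run_log.json` recording the package version, config hash, seed and any
per-animal failures. Re-running with the same config and seed reproduces
the tables byte-for-byte.

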