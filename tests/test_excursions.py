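import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glyco.excursions import (
    BaselineBand,
    DegenerateBandWarning,
    compute_baseline,
    detect_excursions,
    resolve_windows,
    summarize_period,
)
from glyco.io_formats import GlucoseTrace, default_study_design

from .oracles import brute_excursions


def band_for(trace, mean=100.0, sd=10.0):
    return BaselineBand(
        mean=mean, sd=sd, reference_window=(trace.times[0], trace.times[-1]),
        animal_id=trace.animal_id,
    )


class TestComputeBaseline:
    def test_constant_window(self):
        trace = GlucoseTrace.from_values([100.0] * 12, source="repaired")
        band = compute_baseline(trace, (trace.times[0], trace.times[-1]))
        assert band.mean == 100.0
        assert band.sd == 0.0
        assert band.lower == band.upper == 100.0

    def test_two_level_window(self):
        values = [90.0, 110.0] * 6
        trace = GlucoseTrace.from_values(values, source="repaired")
        band = compute_baseline(trace, (trace.times[0], trace.times[-1]))
        assert band.mean == pytest.approx(100.0)
        assert band.sd == pytest.approx(np.std(values, ddof=1))
        assert band.upper - band.lower == pytest.approx(2 * band.sd)

    def test_missing_window_errors(self):
        trace = GlucoseTrace.from_values([100.0] * 20)
        trace = trace.replace(missing=np.ones(20, dtype=bool))
        with pytest.raises(ValueError):
            compute_baseline(trace, (trace.times[0], trace.times[-1]))

    def test_too_few_samples_errors(self):
        trace = GlucoseTrace.from_values([100.0] * 5, source="repaired")
        with pytest.raises(ValueError, match="at least 10"):
            compute_baseline(trace, (trace.times[0], trace.times[-1]))


class TestDetectExcursions:
    def test_worked_example(self, toy_trace):
        band = band_for(toy_trace)
        found = detect_excursions(toy_trace, band)
        peaks = [e for e in found if e.kind == "peak"]
        nadirs = [e for e in found if e.kind == "nadir"]
        assert len(peaks) == 1 and len(nadirs) == 1
        assert peaks[0].duration == 10.0
        assert peaks[0].extremum_value == 130.0
        assert peaks[0].auc == pytest.approx(137.5)
        assert nadirs[0].duration == 5.0
        assert nadirs[0].extremum_value == 80.0
        assert nadirs[0].auc == pytest.approx(37.5)

    def test_inside_band_empty(self):
        trace = GlucoseTrace.from_values([95, 100, 105, 100], source="repaired")
        assert detect_excursions(trace, band_for(trace)) == []

    def test_single_sample_run(self):
        trace = GlucoseTrace.from_values([100, 120, 100], source="repaired")
        found = detect_excursions(trace, band_for(trace))
        assert len(found) == 1
        assert found[0].duration == 0.0
        assert found[0].auc == 0.0

    def test_degenerate_band_warns(self):
        trace = GlucoseTrace.from_values([100, 101, 100], source="repaired")
        with pytest.warns(DegenerateBandWarning):
            found = detect_excursions(trace, band_for(trace, sd=0.0))
        assert len(found) == 1

    def test_shift_equivariance(self, toy_trace):
        band = band_for(toy_trace)
        base = detect_excursions(toy_trace, band)
        shifted = detect_excursions(
            toy_trace.replace(glucose=toy_trace.glucose + 37.0), band.shifted(37.0)
        )
        assert len(base) == len(shifted)
        for a, b in zip(base, shifted):
            assert a.kind == b.kind and a.start == b.start and a.end == b.end
            assert b.extremum_value == pytest.approx(a.extremum_value + 37.0)
            assert b.auc == pytest.approx(a.auc)

    def test_matches_brute_force_scanner(self, rng):
        alphabet = np.array([70.0, 90.0, 100.0, 120.0, 150.0])
        for _ in range(300):
            n = int(rng.integers(1, 16))
            values = alphabet[rng.integers(0, 5, size=n)]
            trace = GlucoseTrace.from_values(values, source="repaired")
            band = band_for(trace, mean=100.0, sd=15.0)
            got = detect_excursions(trace, band)
            want = brute_excursions(values, trace.minutes, band.lower, band.upper)
            assert len(got) == len(want)
            for g, w in zip(got, want):
                assert g.kind == w["kind"]
                assert g.duration == pytest.approx(w["duration"])
                assert g.extremum_value == pytest.approx(w["extremum"])
                assert g.auc == pytest.approx(w["auc"])

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.sampled_from([70.0, 90.0, 100.0, 120.0, 150.0]),
                    min_size=1, max_size=15))
    def test_partition_property(self, values):
        # run memberships plus within-band samples tile the window exactly
        trace = GlucoseTrace.from_values(values, source="repaired")
        band = band_for(trace, 100.0, 15.0)
        found = detect_excursions(trace, band)
        claimed = set()
        for e in found:
            members = [
                i for i, t in enumerate(trace.times) if e.start <= t <= e.end
            ]
            assert not claimed.intersection(members), "excursion runs overlap"
            claimed.update(members)
        inside = {
            i for i, v in enumerate(values) if band.lower <= v <= band.upper
        }
        assert claimed | inside == set(range(len(values)))
        assert claimed & inside == set()


class TestSummarizePeriod:
    def test_worked_example(self, toy_trace):
        band = band_for(toy_trace)
        window = (toy_trace.times[0], toy_trace.times[-1])
        found = detect_excursions(toy_trace, band, window)
        summary = summarize_period(found, toy_trace, band, window)
        assert summary.n_peaks == 1 and summary.n_nadirs == 1
        assert summary.total_peak_auc == pytest.approx(137.5)
        assert summary.total_nadir_auc == pytest.approx(37.5)
        assert summary.max_glucose == 130.0
        assert summary.min_glucose == 80.0
        assert summary.relative_range_pct == pytest.approx(100 * 50 / 130)
        assert summary.frac_above == pytest.approx(0.3)
        assert summary.frac_below == pytest.approx(0.2)
        assert abs(summary.frac_above + summary.frac_below + summary.frac_within_band - 1) < 1e-12

    def test_no_excursions(self):
        trace = GlucoseTrace.from_values([95, 100, 105, 100], source="repaired")
        band = band_for(trace)
        window = (trace.times[0], trace.times[-1])
        summary = summarize_period([], trace, band, window)
        assert summary.n_peaks == summary.n_nadirs == 0
        assert summary.total_peak_auc == 0.0
        assert summary.sharpest_peak is None and summary.sharpest_nadir is None
        assert summary.frac_within_band == 1.0

    def test_equal_maxima_tie_goes_to_earlier(self):
        trace = GlucoseTrace.from_values(
            [100, 130, 100, 130, 100], source="repaired"
        )
        band = band_for(trace)
        window = (trace.times[0], trace.times[-1])
        found = detect_excursions(trace, band, window)
        summary = summarize_period(found, trace, band, window)
        assert summary.n_peaks == 2
        assert summary.sharpest_peak.start == trace.times[1]

    def test_totals_equal_member_sums(self, rng):
        values = 100 + rng.normal(0, 20, 200)
        trace = GlucoseTrace.from_values(values, source="repaired")
        band = band_for(trace, 100, 10)
        window = (trace.times[0], trace.times[-1])
        found = detect_excursions(trace, band, window)
        summary = summarize_period(found, trace, band, window)
        peaks = [e for e in found if e.kind == "peak"]
        nadirs = [e for e in found if e.kind == "nadir"]
        assert summary.total_peak_auc == pytest.approx(
            sum(e.auc for e in peaks), rel=1e-9
        )
        assert summary.total_nadir_duration == pytest.approx(
            sum(e.duration for e in nadirs), rel=1e-9
        )


class TestResolveWindows:
    def test_two_day_trace(self):
        design = default_study_design()
        windows = resolve_windows(
            design, pd.Timestamp("2024-01-01 00:00"), pd.Timestamp("2024-01-02 23:55")
        )
        assert len(windows["night"]) == 1
        assert len(windows["day"]) == 2
        assert len(windows["postprandial"]) == 2

    def test_night_sample_count_on_5min_grid(self):
        design = default_study_design()
        windows = resolve_windows(
            design, pd.Timestamp("2024-01-01 00:00"), pd.Timestamp("2024-01-02 23:55")
        )
        start, end = windows["night"][0]
        n = int((end - start).total_seconds() / 60 / 5) + 1
        assert n == 120  # 21:00 .. 06:55 inclusive

    def test_postprandial_clock_times(self):
        design = default_study_design()
        windows = resolve_windows(
            design, pd.Timestamp("2024-01-01 00:00"), pd.Timestamp("2024-01-01 23:55")
        )
        start, end = windows["postprandial"][0]
        assert start.strftime("%H:%M") == "08:45"
        assert end.strftime("%H:%M") == "13:00"

    def test_empty_span_errors(self):
        with pytest.raises(ValueError):
            resolve_windows(
                default_study_design(),
                pd.Timestamp("2024-01-02"),
                pd.Timestamp("2024-01-01"),
            )
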