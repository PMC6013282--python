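"""Flow-cytometry statistics: calibration, binning arithmetic, histogram
formulas against per-event oracles, regression recovery and the CV bound."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coenocycle import flowstats as fs
from coenocycle.exceptions import (
    EmptyHistogramError,
    InvalidInputError,
    NonGrowingSeriesError,
)
from coenocycle.simulator import AsynchronyEnvelope


def events_frame(intensities, time_h=0.0, condition="c"):
    intensities = np.asarray(intensities, dtype=float)
    return pd.DataFrame(
        {
            "event_id": np.arange(intensities.size),
            "dapi_intensity": intensities,
            "ssc": 1.0,
            "time_h": time_h,
            "condition": condition,
        }
    )


class TestCalibration:
    def test_three_peak_mixture_recovers_reference(self, rng):
        parts = [
            100.0 * p * np.exp(rng.normal(0, 0.05, 2000)) for p in (1, 2, 4)
        ]
        cal = fs.calibrate_reference(np.concatenate(parts))
        assert cal.reference_intensity == pytest.approx(100.0, rel=0.03)

    def test_single_tight_peak(self):
        cal = fs.calibrate_reference(np.full(500, 250.0))
        assert cal.reference_intensity == pytest.approx(250.0, rel=1e-6)

    def test_full_ladder_equal_weights(self, rng):
        ladder = 100.0 * 2.0 ** np.arange(8)  # 1C..128C
        intens = np.concatenate(
            [p * np.exp(rng.normal(0, 0.07, 800)) for p in ladder]
        )
        cal = fs.calibrate_reference(intens)
        assert cal.reference_intensity == pytest.approx(100.0, rel=0.03)

    def test_nonpositive_intensities_rejected(self):
        with pytest.raises(InvalidInputError):
            fs.calibrate_reference(np.array([10.0, -1.0]))

    def test_offset_peaks_warn(self, rng):
        # peaks at 100 and 100*2**1.5 are not a 2-fold ladder
        intens = np.concatenate(
            [
                100.0 * np.exp(rng.normal(0, 0.05, 2000)),
                100.0 * 2 ** 1.5 * np.exp(rng.normal(0, 0.05, 2000)),
            ]
        )
        with pytest.warns(UserWarning, match="log2"):
            fs.calibrate_reference(intens)


class TestAssignPloidy:
    @pytest.mark.parametrize(
        "intensity,expected",
        [
            (412.0, 4.0),   # log2(4.12) = 2.04 -> 4C
            (100.0, 1.0),   # exact reference
            (145.0, 2.0),   # log2(1.45) = 0.536: nearest k=1, residual 0.464
            (800.0, 8.0),
        ],
    )
    def test_binning_arithmetic(self, intensity, expected):
        cal = fs.PloidyCalibration(100.0)
        out = fs.assign_ploidy(events_frame([intensity]), cal)
        assert not out["debris"].iloc[0]
        assert out["ploidy_c"].iloc[0] == expected

    def test_sub_reference_events_are_debris(self):
        cal = fs.PloidyCalibration(100.0)
        out = fs.assign_ploidy(events_frame([60.0, 30.0]), cal)
        assert out["debris"].all()
        assert out["ploidy_c"].isna().all()

    def test_tight_tolerance_flags_between_peak_events(self):
        cal = fs.PloidyCalibration(100.0, bin_tolerance=0.25)
        out = fs.assign_ploidy(events_frame([140.0]), cal)  # log2 = 0.485
        assert out["debris"].iloc[0]

    def test_exact_powers_round_trip_zero_debris(self):
        cal = fs.PloidyCalibration(100.0)
        intens = 100.0 * 2.0 ** np.arange(8)
        out = fs.assign_ploidy(events_frame(intens), cal)
        assert not out["debris"].any()
        assert np.array_equal(out["ploidy_c"], 2.0 ** np.arange(8))
        assert out.attrs["binning"] == {
            "retained": 8, "debris": 0, "reference_intensity": 100.0,
        }


class TestHistogramFormulas:
    def test_histogram_fractions(self):
        cal = fs.PloidyCalibration(100.0)
        binned = fs.assign_ploidy(events_frame([200.0] * 50 + [400.0] * 50), cal)
        hist = fs.ploidy_histogram(binned)
        assert np.array_equal(hist.bins, [2.0, 4.0])
        assert np.allclose(hist.fractions, [0.5, 0.5])
        assert hist.n_events == 100

    def test_all_debris_raises(self):
        cal = fs.PloidyCalibration(100.0)
        binned = fs.assign_ploidy(events_frame([30.0, 40.0]), cal)
        with pytest.raises(EmptyHistogramError):
            fs.ploidy_histogram(binned)

    @pytest.mark.parametrize(
        "fractions,expected",
        [
            ({2.0: 0.5, 4.0: 0.5}, 1.5),
            ({8.0: 1.0}, 3.0),
            ({1.0: 0.25, 2.0: 0.5, 4.0: 0.25}, 1.0),
        ],
    )
    def test_log2_geommean_closed_forms(self, fractions, expected):
        bins = np.array(sorted(fractions))
        hist = fs.PloidyHistogram(
            bins, np.array([fractions[b] for b in bins]), 100
        )
        assert fs.log2_geommean(hist) == pytest.approx(expected, abs=1e-12)

    def test_log2_gsd_modes(self):
        hist = fs.PloidyHistogram(
            np.array([2.0, 4.0]), np.array([0.5, 0.5]), 10
        )
        assert fs.log2_gsd(hist, mode="sqrt") == pytest.approx(0.5, abs=1e-12)
        assert fs.log2_gsd(hist, mode="literal") == pytest.approx(0.25, abs=1e-12)
        degenerate = fs.PloidyHistogram(np.array([4.0]), np.array([1.0]), 10)
        assert fs.log2_gsd(degenerate, "sqrt") == 0.0
        assert fs.log2_gsd(degenerate, "literal") == 0.0
        with pytest.raises(InvalidInputError):
            fs.log2_gsd(hist, mode="median")

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_histogram_stats_match_event_wise_oracle(self, seed):
        # the histogram formulas must equal the plain mean/SD of per-event
        # log2 ploidies (brute-force oracle)
        r = np.random.default_rng(seed)
        ploidies = 2.0 ** r.integers(0, 8, size=r.integers(2, 400))
        hist = fs.histogram_from_ploidies(ploidies)
        log2e = np.log2(ploidies)
        assert fs.log2_geommean(hist) == pytest.approx(log2e.mean(), abs=1e-12)
        assert fs.log2_gsd(hist, "sqrt") == pytest.approx(
            log2e.std(ddof=0), abs=1e-12
        )


class TestDoublingTimeFit:
    def test_noiseless_line_recovered_exactly(self):
        t = np.arange(0.0, 37.0, 3.0)
        fit = fs.fit_doubling_time(t, 0.5 + t / 11.0)
        assert fit.doubling_time_h == pytest.approx(11.0, rel=1e-10)
        assert fit.slope_se == pytest.approx(0.0, abs=1e-8)
        assert fit.n_points == 13

    def test_noisy_series_recovery_monte_carlo(self):
        t = np.arange(0.0, 37.0, 3.0)
        recovered = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            y = 0.5 + t / 11.0 + r.normal(0, 0.05, t.size)
            recovered.append(fs.fit_doubling_time(t, y).doubling_time_h)
        assert 10.5 < np.mean(recovered) < 11.5

    def test_window_restriction(self):
        t = np.arange(0.0, 61.0, 3.0)
        y = 0.5 + t / 11.0
        y[t > 36] = y[t == 36]  # growth stalls after 36 h (burst phase)
        fit = fs.fit_doubling_time(t, y, window=(0.0, 36.0))
        assert fit.doubling_time_h == pytest.approx(11.0, rel=1e-10)

    def test_errors(self):
        t = np.arange(0.0, 37.0, 3.0)
        with pytest.raises(NonGrowingSeriesError):
            fs.fit_doubling_time(t, 2.0 - t / 20.0)
        with pytest.raises(InvalidInputError):
            fs.fit_doubling_time([0.0, 3.0], [0.0, 0.3])


class TestAsynchronySeries:
    def test_delta_subtraction(self):
        series = fs.delta_asynchrony([0.0, 24.0, 48.0], [0.4, 0.5, 0.7])
        assert np.allclose(series.delta_log2gsd, [0.0, 0.1, 0.3])
        assert series.delta_log2gsd[0] == 0.0

    def test_constant_series_all_zero(self):
        series = fs.delta_asynchrony([0.0, 12.0, 24.0], [0.6, 0.6, 0.6])
        assert (series.delta_log2gsd == 0).all()

    def test_missing_baseline_raises(self):
        with pytest.raises(InvalidInputError):
            fs.delta_asynchrony([3.0, 6.0], [0.5, 0.6])


def toy_envelope(cv, mean, sd, grid):
    return AsynchronyEnvelope(
        time_grid=grid,
        mean_delta_log2gsd=np.full(grid.size, mean),
        sd_delta_log2gsd=np.full(grid.size, sd),
        n_replicates=10,
        cv=cv,
    )


class TestCvUpperBound:
    grid = np.arange(0.0, 49.0, 3.0)

    def envelopes(self):
        return [
            toy_envelope(0.025, 0.01, 0.005, self.grid),
            toy_envelope(0.05, 0.05, 0.01, self.grid),
            toy_envelope(0.10, 0.15, 0.01, self.grid),
        ]

    def test_zero_series_returns_smallest_cv(self):
        obs = fs.delta_asynchrony(self.grid, np.full(self.grid.size, 0.3))
        bound = fs.cv_upper_bound(obs, self.envelopes())
        assert bound.cv == 0.025 and bound.bounded

    def test_intermediate_series_skips_small_cv(self):
        g = np.full(self.grid.size, 0.34)
        g[0] = 0.3  # deltas of 0.04 exceed the 0.025 band's upper edge
        obs = fs.delta_asynchrony(self.grid, g)
        bound = fs.cv_upper_bound(obs, self.envelopes())
        assert bound.cv == 0.05 and bound.bounded

    def test_unbounded_series_flagged(self):
        g = 0.3 + np.linspace(0, 0.5, self.grid.size)
        obs = fs.delta_asynchrony(self.grid, g)
        bound = fs.cv_upper_bound(obs, self.envelopes())
        assert bound.cv == 0.10 and not bound.bounded

    def test_unsorted_envelopes_rejected(self):
        obs = fs.delta_asynchrony(self.grid, np.zeros(self.grid.size))
        with pytest.raises(InvalidInputError):
            fs.cv_upper_bound(obs, self.envelopes()[::-1])
        with pytest.raises(InvalidInputError):
            fs.cv_upper_bound(obs, [])

    def test_observed_times_must_be_on_grid(self):
        obs = fs.delta_asynchrony([0.0, 5.0], [0.3, 0.35])
        with pytest.raises(InvalidInputError):
            fs.cv_upper_bound(obs, self.envelopes())


class TestSummaries:
    def test_summarize_timepoints(self):
        cal = fs.PloidyCalibration(100.0)
        frames = [
            events_frame([100.0, 200.0], time_h=0.0),
            events_frame([200.0, 400.0], time_h=12.0),
        ]
        binned = fs.assign_ploidy(pd.concat(frames, ignore_index=True), cal)
        summary = fs.summarize_timepoints(binned)
        assert list(summary["time_h"]) == [0.0, 12.0]
        assert summary["log2_geommean"].tolist() == [0.5, 1.5]

    def test_read_events_validates(self, tmp_path):
        p = tmp_path / "ev.tsv"
        events_frame([100.0, 200.0]).to_csv(p, sep="\t", index=False)
        df = fs.read_events(p)
        assert len(df) == 2
        bad = tmp_path / "bad.tsv"
        events_frame([100.0]).drop(columns=["ssc"]).to_csv(
            bad, sep="\t", index=False
        )
        with pytest.raises(InvalidInputError):
            fs.read_events(bad)
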