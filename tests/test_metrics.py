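import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fidgetkit as fk
from fidgetkit.metrics import combine_axes, combine_sensor_tables

from conftest import make_movement, sine_movement


def brute_force_peaks(values, threshold=0.0):
    """Triple-comparison scan; plateau collapsed to its first sample."""
    idx = []
    i = 1
    n = len(values)
    while i < n - 1:
        j = i
        while j < n - 1 and values[j + 1] == values[j]:
            j += 1
        if values[i] > values[i - 1] and j < n - 1 and values[j] > values[j + 1]:
            if values[i] > threshold:
                idx.append(i)
        i = j + 1
    return idx


def peaks_at(times_ms, heights=None, axis="x", site="wrist"):
    times_ms = np.asarray(times_ms, dtype=float)
    if heights is None:
        heights = np.ones_like(times_ms)
    return fk.PeakSeries(times_ms, np.asarray(heights, float), axis, site)


class TestDetectPeaks:
    def test_two_hz_sine_has_four_peaks(self):
        mov = sine_movement(2.0, 2.0)
        peaks = fk.detect_peaks(mov, threshold=0.5)["x"]
        assert peaks.n_peaks == 4
        np.testing.assert_allclose(peaks.peak_heights, 1.0, atol=1e-4)

    def test_zero_signal_has_no_peaks(self):
        peaks = fk.detect_peaks(make_movement(np.zeros(500)))
        assert all(peaks[ax].n_peaks == 0 for ax in ("x", "y", "z"))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=200)
        mov = make_movement(values, rate=1000.0)
        got = fk.detect_peaks(mov, threshold=0.0)["x"]
        expected = brute_force_peaks(values)
        np.testing.assert_array_equal(got.peak_times_ms, np.asarray(expected, float))
        np.testing.assert_array_equal(got.peak_heights, values[expected])

    def test_plateau_collapses_to_first_sample(self):
        values = np.array([0.0, 1.0, 1.0, 1.0, 0.0, 2.0, 0.0])
        got = fk.detect_peaks(make_movement(values, rate=1000.0))["x"]
        np.testing.assert_array_equal(got.peak_times_ms, [1.0, 5.0])

    def test_threshold_excludes_low_peaks(self):
        values = np.array([0.0, 0.4, 0.0, 0.9, 0.0])
        got = fk.detect_peaks(make_movement(values, rate=1000.0), threshold=0.5)["x"]
        assert got.n_peaks == 1
        assert got.peak_heights[0] == 0.9

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            fk.detect_peaks(make_movement([0.0, 1.0]))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_brute_force_property(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=120)
        got = fk.detect_peaks(make_movement(values, rate=1000.0))["x"]
        assert list(got.peak_times_ms) == [float(i) for i in brute_force_peaks(values)]


class TestComputeFidgetMetrics:
    def test_equally_spaced_peaks(self):
        m = fk.compute_fidget_metrics(
            peaks_at([0, 200, 400, 600], heights=[2.0] * 4), (0, 1000)
        )
        assert m.number_of_fidgets == 4
        assert m.fidget_time_variability == 0.0
        assert m.fidget_intensity == 2.0

    def test_hand_computed_variance(self):
        # intervals {100, 200}: population variance 2500 ms^2
        m = fk.compute_fidget_metrics(peaks_at([0, 100, 300]), (0, 1000))
        assert m.fidget_time_variability == pytest.approx(2500.0)

    def test_two_peaks_variability_undefined(self):
        m = fk.compute_fidget_metrics(peaks_at([0, 100]), (0, 1000))
        assert m.fidget_time_variability is None
        assert m.fidget_intensity == 1.0

    def test_no_peaks_intensity_undefined(self):
        m = fk.compute_fidget_metrics(peaks_at([]), (0, 1000))
        assert m.number_of_fidgets == 0
        assert m.fidget_intensity is None

    def test_window_is_half_open(self):
        m = fk.compute_fidget_metrics(peaks_at([0, 500, 1000]), (0, 1000))
        assert m.number_of_fidgets == 2

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            fk.compute_fidget_metrics(peaks_at([0]), (100, 100))

    def test_peak_count_additive_over_partition(self):
        rng = np.random.default_rng(5)
        times = np.sort(rng.uniform(0, 2000, 25))
        series = peaks_at(times)
        whole = fk.compute_fidget_metrics(series, (0, 2000))
        parts = [
            fk.compute_fidget_metrics(series, (a, b))
            for a, b in [(0, 500), (500, 1200), (1200, 2000)]
        ]
        assert whole.number_of_fidgets == sum(p.number_of_fidgets for p in parts)

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=300)
        c = 3.7
        base = fk.compute_fidget_metrics(
            fk.detect_peaks(make_movement(values, rate=1000.0), 0.2)["x"], (0, 300)
        )
        scaled = fk.compute_fidget_metrics(
            fk.detect_peaks(make_movement(c * values, rate=1000.0), c * 0.2)["x"],
            (0, 300),
        )
        assert scaled.number_of_fidgets == base.number_of_fidgets
        assert scaled.fidget_time_variability == pytest.approx(
            base.fidget_time_variability
        )
        assert scaled.fidget_intensity == pytest.approx(c * base.fidget_intensity)


class TestCombineSensors:
    def test_table3_number_of_fidgets_convention(self):
        arm = fk.FidgetMetrics(2.1, 131.3, 0.1)
        leg = fk.FidgetMetrics(2.6, 135.5, 0.5)
        combo = fk.combine_sensors(arm, leg)
        assert combo.number_of_fidgets == pytest.approx(4.7)
        assert combo.fidget_intensity == pytest.approx(0.6)
        assert combo.fidget_time_variability == pytest.approx(266.8)

    def test_zero_leg_is_identity(self):
        arm = fk.FidgetMetrics(3.0, 100.0, 0.4)
        leg = fk.FidgetMetrics(0.0, 0.0, 0.0)
        combo = fk.combine_sensors(arm, leg)
        assert combo.number_of_fidgets == 3.0
        assert combo.fidget_time_variability == 100.0
        assert combo.fidget_intensity == pytest.approx(0.4)

    def test_commutative(self):
        a = fk.FidgetMetrics(1.0, 50.0, 0.2)
        b = fk.FidgetMetrics(2.0, None, 0.3)
        ab, ba = fk.combine_sensors(a, b), fk.combine_sensors(b, a)
        assert ab == ba

    def test_associative(self):
        ms = [fk.FidgetMetrics(i + 1.0, 10.0 * i, 0.1 * i) for i in range(3)]
        left = fk.combine_sensors(fk.combine_sensors(ms[0], ms[1]), ms[2])
        right = fk.combine_sensors(ms[0], fk.combine_sensors(ms[1], ms[2]))
        assert left.number_of_fidgets == right.number_of_fidgets
        assert left.fidget_time_variability == pytest.approx(
            right.fidget_time_variability
        )

    def test_undefined_propagates_only_when_both_undefined(self):
        a = fk.FidgetMetrics(0.0, None, None)
        b = fk.FidgetMetrics(2.0, 40.0, 0.3)
        assert fk.combine_sensors(a, b).fidget_intensity == pytest.approx(0.3)
        assert fk.combine_sensors(a, a).fidget_intensity is None


class TestEpochMetrics:
    def test_120_trial_schedule_gives_120_rows(self):
        sch = fk.TaskSchedule(seed=2)
        prof = fk.FidgetProfile(bout_occupancy=0.5, noise_sd=0.02)
        rec = fk.simulate_recording(prof, sch, sample_rate_hz=100.0, seed=3)
        filt = fk.band_reconstruct(fk.differentiate(rec), fk.FrequencyBand(1, 20))
        table = fk.epoch_metrics(filt, sch.events(), threshold=0.2)
        assert len(table) == 120
        assert set(table["trial_index"]) == set(range(120))

    def test_planted_late_bouts_raise_late_counts(self):
        sch = fk.TaskSchedule(seed=4)
        occ = np.zeros(120)
        occ[90:] = 0.8
        prof = fk.FidgetProfile(bout_occupancy=occ, noise_sd=0.0)
        rec = fk.simulate_recording(prof, sch, sample_rate_hz=100.0, seed=5)
        filt = fk.band_reconstruct(fk.differentiate(rec), fk.FrequencyBand(1, 20))
        table = fk.epoch_metrics(filt, sch.events(), threshold=0.3)
        counts = table.sort_values("trial_index")["n_fidgets"].to_numpy()
        assert counts[90:].mean() > counts[:30].mean()

    def test_empty_movement_gives_zero_counts(self):
        sch = fk.TaskSchedule(n_per_type=2, seed=0)
        n = int(sch.duration_s * 100)
        table = fk.epoch_metrics(make_movement(np.zeros(n), rate=100.0), sch.events())
        assert (table["n_fidgets"] == 0).all()
        assert table["intensity"].isna().all()

    def test_stimulus_only_epoch_is_half_window(self):
        sch = fk.TaskSchedule(n_per_type=1, seed=0)
        rec = fk.simulate_recording(
            fk.FidgetProfile(bout_occupancy=1.0), sch, sample_rate_hz=500.0, seed=0
        )
        filt = fk.band_reconstruct(fk.differentiate(rec), fk.FrequencyBand(1, 20))
        full = fk.epoch_metrics(filt, sch.events(), epoch="stimulus_plus_iti")
        half = fk.epoch_metrics(filt, sch.events(), epoch="stimulus_only")
        assert (half["n_fidgets"] * 2 == full["n_fidgets"]).all()

    def test_events_outside_span_rejected(self):
        mov = make_movement(np.zeros(100), rate=100.0)  # 1 s span
        sch = fk.TaskSchedule(n_per_type=1, seed=0)  # needs 6 s
        with pytest.raises(ValueError):
            fk.epoch_metrics(mov, sch.events())


class TestCombineSensorTables:
    def test_rowwise_sum(self):
        arm = pd.DataFrame(
            {
                "trial_index": [0, 1],
                "sensor_site": "wrist",
                "n_fidgets": [2.0, 3.0],
                "variability_ms2": [100.0, np.nan],
                "intensity": [0.1, 0.2],
                "trial_type": ["congruent", "neutral"],
                "correct": [True, True],
                "rt_ms": [400.0, 380.0],
            }
        )
        leg = arm.copy()
        leg["sensor_site"] = "ankle"
        leg["n_fidgets"] = [4.0, 1.0]
        leg["variability_ms2"] = [50.0, np.nan]
        combo = combine_sensor_tables(arm, leg)
        assert list(combo["n_fidgets"]) == [6.0, 4.0]
        assert combo["variability_ms2"].iloc[0] == 150.0
        assert np.isnan(combo["variability_ms2"].iloc[1])


class TestAggregateMetrics:
    @staticmethod
    def table_from(counts, variabilities, intensities):
        return pd.DataFrame(
            {
                "trial_index": range(len(counts)),
                "sensor_site": "wrist",
                "n_fidgets": counts,
                "variability_ms2": variabilities,
                "intensity": intensities,
            }
        )

    def test_identical_trials_mean_and_zero_sd(self):
        t = self.table_from([3.0] * 10, [40.0] * 10, [0.5] * 10)
        agg = fk.aggregate_metrics(t)
        assert agg.loc["n_fidgets", "mean"] == 3.0
        assert agg.loc["n_fidgets", "sd"] == 0.0

    def test_single_trial_subset(self):
        t = self.table_from([1.0, 5.0], [10.0, 20.0], [0.1, 0.9])
        agg = fk.aggregate_metrics(t, subset=[False, True])
        assert agg.loc["n_fidgets", "mean"] == 5.0
        assert agg.loc["intensity", "mean"] == pytest.approx(0.9)

    def test_matches_hand_rolled_mean_sd(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 10, 50).astype(float)
        var = rng.uniform(0, 200, 50)
        inten = rng.uniform(0, 1, 50)
        agg = fk.aggregate_metrics(self.table_from(counts, var, inten))
        assert agg.loc["variability_ms2", "mean"] == pytest.approx(
            var.mean(), abs=1e-12
        )
        assert agg.loc["variability_ms2", "sd"] == pytest.approx(
            var.std(ddof=1), abs=1e-12
        )

    def test_nan_skipped_with_count(self):
        t = self.table_from([1.0, 2.0, 3.0], [np.nan, 10.0, 20.0], [0.1, np.nan, 0.3])
        agg = fk.aggregate_metrics(t)
        assert agg.loc["variability_ms2", "n_trials"] == 2
        assert agg.loc["variability_ms2", "mean"] == 15.0

    def test_empty_subset_rejected(self):
        t = self.table_from([1.0], [10.0], [0.1])
        with pytest.raises(ValueError):
            fk.aggregate_metrics(t, subset=[False])


class TestCombineAxes:
    def test_planted_single_axis_bout_ground_truth(self):
        # noiseless 5 Hz bout filling a 2 s epoch: 10 peaks, variability 0,
        # intensity equal to the planted amplitude
        sch = fk.TaskSchedule(n_per_type=1, seed=0)
        prof = fk.FidgetProfile(bout_frequency_hz=5.0, bout_amplitude=2.0)
        rec = fk.simulate_recording(prof, sch, sample_rate_hz=500.0, seed=0)
        filt = fk.band_reconstruct(fk.differentiate(rec), fk.FrequencyBand(1, 20))
        m = fk.compute_fidget_metrics(fk.detect_peaks(filt, 0.5), (0.0, 2000.0))
        assert m.number_of_fidgets == 10
        assert m.fidget_time_variability == 0.0
        assert m.fidget_intensity == pytest.approx(2.0, rel=0.01)

    def test_empty_axis_list_rejected(self):
        with pytest.raises(ValueError):
            combine_axes([])
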