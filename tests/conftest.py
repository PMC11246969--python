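import numpy as np
import pytest
from scipy import stats

import fidgetkit as fk


@pytest.fixture
def schedule():
    return fk.TaskSchedule()


@pytest.fixture
def small_schedule():
    """One trial per type: short sessions for fast signal tests."""
    return fk.TaskSchedule(n_per_type=1, seed=0)


def make_movement(values, rate=500.0, site="wrist", start_ms=0.0):
    """Wrap a 1-d array as a single-axis movement signal (y, z zero)."""
    values = np.asarray(values, dtype=float)
    stacked = np.column_stack([values, np.zeros_like(values), np.zeros_like(values)])
    return fk.MovementSignal(
        sensor_site=site, sample_rate_hz=rate, values=stacked, start_time_ms=start_ms
    )


def sine_movement(freq_hz, duration_s, rate=500.0, amplitude=1.0):
    t = np.arange(int(round(duration_s * rate))) / rate
    return make_movement(amplitude * np.sin(2 * np.pi * freq_hz * t), rate=rate)


def q1q4_cohort_pvalue(rep_seed, n_participants=40, effect=True):
    """Full-pipeline paired Q1-vs-Q4 p-value for one synthetic cohort.

    Each participant runs a 30-trial session at 50 Hz with per-trial bout
    occupancy; under ``effect`` the last-quarter occupancy is raised by a
    1-SD (mean 0.15, SD 0.15) within-participant increment.
    """

    def one_participant(seed):
        rng = np.random.default_rng(seed)
        sch = fk.TaskSchedule(n_per_type=10, seed=seed)
        base = rng.uniform(0.3, 0.5)
        occ = np.clip(rng.normal(base, 0.08, sch.n_trials), 0.05, 0.95)
        qn = sch.n_trials // 4
        if effect:
            delta = rng.normal(0.15, 0.15)
            occ[-qn:] = np.clip(occ[-qn:] + delta, 0.05, 0.95)
        profile = fk.FidgetProfile(bout_occupancy=occ, noise_sd=0.05)
        rec = fk.simulate_recording(profile, sch, sample_rate_hz=50.0, seed=seed + 1)
        filtered = fk.band_reconstruct(fk.differentiate(rec), fk.FrequencyBand(1, 20))
        table = fk.epoch_metrics(filtered, sch.events(), threshold=0.3)
        counts = table["n_fidgets"].to_numpy()
        return counts[:qn].mean(), counts[-qn:].mean()

    pairs = [one_participant(rep_seed * 1000 + i) for i in range(n_participants)]
    q1, q4 = map(np.asarray, zip(*pairs))
    return float(stats.ttest_rel(q4, q1).pvalue)
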