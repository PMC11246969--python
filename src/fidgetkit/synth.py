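"""Seeded synthetic actigraphy, reaction times and participant cohorts
with planted ground truth.

The generator synthesizes the *movement* (derivative) signal first —
band-limited sinusoidal bouts plus white device noise and an optional
high-frequency artifact tone — and cumulatively sums it into position
samples.  Because the analysis pipeline begins by differentiating raw
position data, this guarantees exactly known ground truth after the
derivative step.  Signal units are arbitrary (device amplitude scales are
not standardized).

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from fidgetkit.analysis import SCALE_RANGES, ParticipantRecord
from fidgetkit.metrics import FidgetMetrics
from fidgetkit.rt import ExGaussianParams
from fidgetkit.signal import AccelerometerRecording
from fidgetkit.task import TaskSchedule, TrialEvent

CALIBRATION_KINDS = ("stationary", "simulated_fidget", "rapid")

#: order of the six fidget predictors used for scale-total coupling
PREDICTOR_ORDER = (
    "arm_n_fidgets",
    "arm_variability",
    "arm_intensity",
    "leg_n_fidgets",
    "leg_variability",
    "leg_intensity",
)

# cohort-scale predictor distributions (lognormal mean, sd per predictor)
_PREDICTOR_MEANS = np.array([2.1, 131.3, 0.1, 2.6, 135.5, 0.5])
_PREDICTOR_SDS = np.array([1.5, 103.7, 0.2, 1.4, 80.4, 0.9])


@dataclass(frozen=True)
class FidgetProfile:
    """Planted fidget-bout structure of a synthetic recording.

    ``bout_occupancy`` may be a scalar or a per-trial sequence of
    fractions in [0, 1].  ``hf_artifact_hz`` models device noise above
    the analysis band.
    """

    bout_frequency_hz: float = 5.0
    bout_amplitude: float = 1.0
    bout_occupancy: float | Sequence[float] = 1.0
    noise_sd: float = 0.0
    hf_artifact_hz: float | None = None
    hf_artifact_amplitude: float = 0.0
    band_low_hz: float = 1.0
    band_high_hz: float = 20.0

    def __post_init__(self) -> None:
        if not (self.band_low_hz < self.bout_frequency_hz < self.band_high_hz):
            raise ValueError("bout frequency must lie strictly inside the band")
        if self.bout_amplitude <= 0:
            raise ValueError("bout_amplitude must be > 0")
        if self.noise_sd < 0 or self.hf_artifact_amplitude < 0:
            raise ValueError("noise and artifact amplitudes must be >= 0")
        if self.hf_artifact_hz is not None and self.hf_artifact_hz <= self.band_high_hz:
            raise ValueError("hf_artifact_hz must exceed the band high edge")
        occ = np.atleast_1d(np.asarray(self.bout_occupancy, dtype=float))
        if np.any((occ < 0) | (occ > 1)):
            raise ValueError("bout occupancy must be within [0, 1]")

    def occupancy_per_trial(self, n_trials: int) -> np.ndarray:
        occ = np.atleast_1d(np.asarray(self.bout_occupancy, dtype=float))
        if occ.size == 1:
            return np.full(n_trials, occ[0])
        if occ.size != n_trials:
            raise ValueError(
                f"per-trial occupancy has {occ.size} entries for {n_trials} trials"
            )
        return occ


def _check_nyquist(profile: FidgetProfile, sample_rate_hz: float) -> None:
    top = max(profile.bout_frequency_hz, profile.hf_artifact_hz or 0.0)
    if sample_rate_hz <= 2 * top:
        raise ValueError(
            f"sample rate {sample_rate_hz} Hz violates Nyquist for {top} Hz content"
        )


def _integrate(movement: np.ndarray, sample_rate_hz: float, site: str) -> AccelerometerRecording:
    """Cumulative-sum movement into position so the forward difference
    recovers the planted movement signal."""
    position = np.vstack(
        [np.zeros((1, 3)), np.cumsum(movement / sample_rate_hz, axis=0)]
    )
    return AccelerometerRecording(
        sensor_site=site, sample_rate_hz=sample_rate_hz, samples=position
    )


def simulate_recording(
    profile: FidgetProfile,
    schedule: TaskSchedule,
    sample_rate_hz: float = 500.0,
    seed: int = 0,
    sensor_site: str = "wrist",
) -> AccelerometerRecording:
    """Full-session 3-axis recording with planted fidget bouts.

    Each trial's bout is a contiguous interval at the start of the trial
    covering its occupied fraction; within a bout the x-axis movement is
    a sinusoid at ``bout_frequency_hz`` with the planted amplitude
    (phase zero at bout start).  White noise is added on all axes, plus
    the optional high-frequency artifact tone.
    """
    _check_nyquist(profile, sample_rate_hz)
    rng = np.random.default_rng(seed)
    n_m = int(round(schedule.duration_s * sample_rate_hz))
    t = np.arange(n_m) / sample_rate_hz  # seconds
    movement = rng.standard_normal((n_m, 3)) * profile.noise_sd

    occ = profile.occupancy_per_trial(schedule.n_trials)
    trial_s = schedule.trial_ms / 1000.0
    for onset_ms, frac in zip(schedule.onsets_ms(), occ):
        if frac <= 0:
            continue
        start_s = onset_ms / 1000.0
        mask = (t >= start_s) & (t < start_s + frac * trial_s)
        movement[mask, 0] += profile.bout_amplitude * np.sin(
            2 * np.pi * profile.bout_frequency_hz * (t[mask] - start_s)
        )
    if profile.hf_artifact_hz is not None and profile.hf_artifact_amplitude > 0:
        tone = profile.hf_artifact_amplitude * np.sin(
            2 * np.pi * profile.hf_artifact_hz * t
        )
        movement += tone[:, None]
    return _integrate(movement, sample_rate_hz, sensor_site)


def simulate_calibration(
    kind: str,
    duration_s: float = 60.0,
    seed: int = 0,
    profile: FidgetProfile | None = None,
    sample_rate_hz: float = 500.0,
    sensor_site: str = "wrist",
) -> AccelerometerRecording:
    """Calibration recording of one of three movement regimes.

    stationary        noise only (device at rest)
    simulated_fidget  sustained sinusoidal bout inside the analysis band
    rapid             broadband movement, stronger and more erratic than
                      fidgeting (its energy above the band high edge
                      exceeds the simulated_fidget case)
    """
    if kind not in CALIBRATION_KINDS:
        raise ValueError(f"unknown calibration kind {kind!r}")
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    profile = profile or FidgetProfile(noise_sd=0.02)
    _check_nyquist(profile, sample_rate_hz)
    rng = np.random.default_rng(seed)
    n_m = int(round(duration_s * sample_rate_hz))
    t = np.arange(n_m) / sample_rate_hz
    movement = rng.standard_normal((n_m, 3)) * profile.noise_sd
    if kind == "simulated_fidget":
        movement[:, 0] += profile.bout_amplitude * np.sin(
            2 * np.pi * profile.bout_frequency_hz * t
        )
    elif kind == "rapid":
        strength = 3.0 * max(profile.bout_amplitude, profile.noise_sd)
        movement += strength * rng.standard_normal((n_m, 3))
    if profile.hf_artifact_hz is not None and profile.hf_artifact_amplitude > 0:
        movement += (
            profile.hf_artifact_amplitude
            * np.sin(2 * np.pi * profile.hf_artifact_hz * t)[:, None]
        )
    return _integrate(movement, sample_rate_hz, sensor_site)


def simulate_reaction_times(
    params: ExGaussianParams,
    n: int,
    omission_rate: float = 0.0,
    seed: int = 0,
    p_error: float = 0.0,
    schedule: TaskSchedule | None = None,
) -> list[TrialEvent]:
    """Trial events with ex-Gaussian reaction times and random omissions.

    Non-omitted RTs are Normal(mu, sigma) + Exponential(mean tau) draws;
    omissions are missing at random at ``omission_rate``.  Trial types
    follow ``schedule`` when given (its length must then be ``n``),
    otherwise cycle through the three types.
    """
    if not (0 <= omission_rate < 1):
        raise ValueError("omission_rate must be in [0, 1)")
    if not (0 <= p_error < 1):
        raise ValueError("p_error must be in [0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    if schedule is not None and schedule.n_trials != n:
        raise ValueError("schedule length does not match n")
    rng = np.random.default_rng(seed)
    rts = rng.normal(params.mu, params.sigma, size=n) + rng.exponential(
        params.tau, size=n
    )
    rts = np.maximum(rts, 1.0)  # RTs are positive by contract
    omitted = rng.random(n) < omission_rate
    errors = rng.random(n) < p_error
    sides = rng.choice(["left", "right"], size=n)

    if schedule is not None:
        types = schedule.trial_types
        onsets = schedule.onsets_ms()
        trial_ms = schedule.trial_ms
    else:
        types = tuple(
            ("congruent", "incongruent", "neutral")[i % 3] for i in range(n)
        )
        onsets = np.arange(n) * 2000.0
        trial_ms = 2000.0

    events = []
    for i in range(n):
        if omitted[i]:
            events.append(
                TrialEvent(i, types[i], float(onsets[i]), "none", False, None)
            )
        else:
            events.append(
                TrialEvent(
                    i,
                    types[i],
                    float(onsets[i]),
                    str(sides[i]),
                    bool(not errors[i]),
                    float(min(rts[i], trial_ms)),
                )
            )
    return events


def noise_sd_for_target_r(coefficients: np.ndarray, target_r: float) -> float:
    """Residual noise SD giving population multiple correlation
    ``target_r`` for the default predictor distributions."""
    if not (0 < target_r < 1):
        raise ValueError("target_r must be in (0, 1)")
    coefficients = np.asarray(coefficients, dtype=float)
    signal_var = float(np.sum((coefficients * _PREDICTOR_SDS) ** 2))
    return float(np.sqrt(signal_var * (1.0 / target_r**2 - 1.0)))


def _lognormal_params(mean: np.ndarray, sd: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    var = sd**2
    sigma2 = np.log1p(var / mean**2)
    mu = np.log(mean) - sigma2 / 2
    return mu, np.sqrt(sigma2)


def simulate_participants(
    n: int,
    coupling: dict[str, tuple[float, Sequence[float]]] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[ParticipantRecord]:
    """Cohort with scale totals linearly coupled to fidget variables.

    ``coupling`` maps a scale name ("baars" | "bdefs_sec5" | "ari") to
    ``(intercept, six coefficients)`` in ``PREDICTOR_ORDER``.  Each total
    is intercept + coefficients . predictors + Normal(0, noise_sd) noise,
    clipped to the scale's legal range.  The six predictors are lognormal
    with the package's default cohort-scale means and SDs, so their
    variances are exact (no truncation).
    """
    if n < 8:
        raise ValueError("need n >= 8 (more observations than 6 predictors + 1)")
    coupling = coupling or {}
    for scale in coupling:
        if scale not in SCALE_RANGES:
            raise ValueError(f"unknown scale {scale!r}")
    rng = np.random.default_rng(seed)
    lmu, lsig = _lognormal_params(_PREDICTOR_MEANS, _PREDICTOR_SDS)
    X = rng.lognormal(lmu, lsig, size=(n, 6))

    mus = np.clip(rng.normal(369.3, 46.2, n), 150.0, None)
    sigmas = np.clip(rng.normal(51.9, 18.4, n), 5.0, None)
    taus = np.clip(rng.normal(70.0, 26.5, n), 5.0, None)
    flanker_totals = np.clip(np.rint(rng.normal(115.5, 7.5, n)), 0, 120)
    digit_span = np.clip(rng.normal(10.9, 3.1, n), 0, None)
    stroop_color = np.clip(rng.normal(70.4, 12.5, n), 0, None)
    stroop_cw = np.clip(rng.normal(49.7, 9.0, n), 0, None)

    records = []
    for i in range(n):
        totals = {}
        for scale, (lo, hi) in SCALE_RANGES.items():
            if scale in coupling:
                intercept, coefs = coupling[scale]
                coefs = np.asarray(coefs, dtype=float)
                raw = intercept + float(X[i] @ coefs)
            else:
                raw = (lo + hi) / 2.0
            raw += rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            totals[scale] = float(np.clip(raw, lo, hi))
        records.append(
            ParticipantRecord(
                participant_id=f"P{i:03d}",
                fidget_arm=FidgetMetrics(X[i, 0], X[i, 1], X[i, 2]),
                fidget_leg=FidgetMetrics(X[i, 3], X[i, 4], X[i, 5]),
                rt_params=ExGaussianParams(
                    float(mus[i]), float(sigmas[i]), float(taus[i])
                ),
                flanker_total=int(flanker_totals[i]),
                baars=totals["baars"],
                bdefs_sec5=totals["bdefs_sec5"],
                ari=totals["ari"],
                digit_span=float(digit_span[i]),
                stroop_color=float(stroop_color[i]),
                stroop_color_word=float(stroop_cw[i]),
            )
        )
    return records
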