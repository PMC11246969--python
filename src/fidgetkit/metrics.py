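"""Peak detection and the three per-trial fidget variables.

A peak is a sample strictly greater than both neighbors; a plateau of
equal values flanked by lower samples yields one peak at its first sample.
Per epoch the variables are:

* number of fidgets — count of peaks in the window,
* fidget time variability — population variance (ms^2) of consecutive
  inter-peak intervals, undefined with fewer than 3 peaks,
* fidget intensity — mean peak height, undefined with no peaks.

Per-axis results are combined by summation (counts, variabilities and
intensities each summed over the three axes), the same rule used to
combine sensors (arm + leg).  Undefined values are flagged (``None`` /
``NaN``), never zero-filled: zero variability would conflate "no
fidgeting" with "perfectly regular fidgeting".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from fidgetkit.signal import AXES, MovementSignal
from fidgetkit.task import TrialEvent

EPOCH_MODES = ("stimulus_only", "stimulus_plus_iti")

METRIC_COLUMNS = ("n_fidgets", "variability_ms2", "intensity")


@dataclass(frozen=True)
class PeakSeries:
    """Detected peaks on one axis of one sensor's movement signal."""

    peak_times_ms: np.ndarray  # strictly increasing
    peak_heights: np.ndarray
    axis: str
    sensor_site: str

    def __post_init__(self) -> None:
        times = np.asarray(self.peak_times_ms, dtype=float)
        heights = np.asarray(self.peak_heights, dtype=float)
        if times.shape != heights.shape or times.ndim != 1:
            raise ValueError("times and heights must be matching 1-d arrays")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("peak times must be strictly increasing")
        object.__setattr__(self, "peak_times_ms", times)
        object.__setattr__(self, "peak_heights", heights)

    @property
    def n_peaks(self) -> int:
        return self.peak_times_ms.size


@dataclass(frozen=True)
class FidgetMetrics:
    """The fidget-variable triple for one epoch (or aggregate) of one
    sensor (or sensor combination).  ``None`` marks an undefined value."""

    number_of_fidgets: float
    fidget_time_variability: float | None  # ms^2
    fidget_intensity: float | None

    def __post_init__(self) -> None:
        if self.number_of_fidgets < 0:
            raise ValueError("number_of_fidgets must be >= 0")
        if self.fidget_time_variability is not None and self.fidget_time_variability < 0:
            raise ValueError("variability must be >= 0")


def _plateau_peaks(values: np.ndarray, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Indices and heights of strict local maxima, plateaus collapsed to
    their first sample."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("signal must have at least 3 samples")
    # compress runs of equal values; keep the first index of each run
    change = np.empty(values.size, dtype=bool)
    change[0] = True
    np.not_equal(values[1:], values[:-1], out=change[1:])
    run_starts = np.flatnonzero(change)
    run_vals = values[run_starts]
    if run_vals.size < 3:
        return np.empty(0, dtype=int), np.empty(0)
    interior = (run_vals[1:-1] > run_vals[:-2]) & (run_vals[1:-1] > run_vals[2:])
    peak_idx = run_starts[1:-1][interior]
    heights = values[peak_idx]
    over = heights > threshold
    return peak_idx[over], heights[over]


def detect_peaks(movement: MovementSignal, threshold: float = 0.0) -> dict[str, PeakSeries]:
    """Detect peaks on each axis of a (band-limited) movement signal.

    The band-limited-input contract is documented, not enforced.  Only
    peaks with height strictly above ``threshold`` are returned.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    step_ms = 1000.0 / movement.sample_rate_hz
    out: dict[str, PeakSeries] = {}
    for ax in AXES:
        idx, heights = _plateau_peaks(movement.axis(ax), threshold)
        out[ax] = PeakSeries(
            peak_times_ms=movement.start_time_ms + idx * step_ms,
            peak_heights=heights,
            axis=ax,
            sensor_site=movement.sensor_site,
        )
    return out


def _window_metrics(peaks: PeakSeries, start_ms: float, end_ms: float) -> FidgetMetrics:
    inside = (peaks.peak_times_ms >= start_ms) & (peaks.peak_times_ms < end_ms)
    times = peaks.peak_times_ms[inside]
    heights = peaks.peak_heights[inside]
    n = times.size
    variability = float(np.var(np.diff(times))) if n >= 3 else None
    intensity = float(np.mean(heights)) if n >= 1 else None
    return FidgetMetrics(float(n), variability, intensity)


def _sum_optional(values: list[float | None]) -> float | None:
    defined = [v for v in values if v is not None]
    return sum(defined) if defined else None


def combine_axes(per_axis: list[FidgetMetrics]) -> FidgetMetrics:
    """Sum the three variables across axes; an axis with an undefined
    value is skipped, and the combination is undefined only when every
    axis is."""
    if not per_axis:
        raise ValueError("need at least one axis")
    return FidgetMetrics(
        number_of_fidgets=sum(m.number_of_fidgets for m in per_axis),
        fidget_time_variability=_sum_optional(
            [m.fidget_time_variability for m in per_axis]
        ),
        fidget_intensity=_sum_optional([m.fidget_intensity for m in per_axis]),
    )


def compute_fidget_metrics(
    peaks: PeakSeries | dict[str, PeakSeries] | list[PeakSeries],
    window: tuple[float, float],
) -> FidgetMetrics:
    """Fidget variables for the half-open window [start_ms, end_ms).

    A single ``PeakSeries`` gives one-axis metrics; a dict or list of
    series is combined across axes by summation.
    """
    start_ms, end_ms = window
    if end_ms <= start_ms:
        raise ValueError("window must be non-empty")
    if isinstance(peaks, PeakSeries):
        return _window_metrics(peaks, start_ms, end_ms)
    series = list(peaks.values()) if isinstance(peaks, dict) else list(peaks)
    return combine_axes([_window_metrics(s, start_ms, end_ms) for s in series])


def epoch_metrics(
    movement: MovementSignal,
    events: list[TrialEvent],
    epoch: str = "stimulus_plus_iti",
    threshold: float = 0.0,
    stimulus_ms: float = 1000.0,
    iti_ms: float = 1000.0,
) -> pd.DataFrame:
    """One row of fidget metrics per trial for one sensor.

    Epoch windows are [onset, onset + stimulus_ms) or
    [onset, onset + stimulus_ms + iti_ms) per ``epoch``
    (default stimulus plus ITI).  Columns: trial_index, sensor_site,
    n_fidgets, variability_ms2, intensity, trial_type, correct, rt_ms.
    """
    if epoch not in EPOCH_MODES:
        raise ValueError(f"epoch must be one of {EPOCH_MODES}")
    if not events:
        raise ValueError("no trial events")
    onsets = [e.onset_ms for e in events]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("events must be sorted by onset")
    window_ms = stimulus_ms if epoch == "stimulus_only" else stimulus_ms + iti_ms
    span_end = movement.start_time_ms + movement.n_samples * 1000.0 / movement.sample_rate_hz
    if onsets[0] < movement.start_time_ms or onsets[-1] + window_ms > span_end + 1e-6:
        raise ValueError("trial epochs extend outside the recording span")

    per_axis = detect_peaks(movement, threshold=threshold)
    rows = []
    for e in events:
        m = compute_fidget_metrics(per_axis, (e.onset_ms, e.onset_ms + window_ms))
        rows.append(
            {
                "trial_index": e.trial_index,
                "sensor_site": movement.sensor_site,
                "n_fidgets": m.number_of_fidgets,
                "variability_ms2": math.nan
                if m.fidget_time_variability is None
                else m.fidget_time_variability,
                "intensity": math.nan
                if m.fidget_intensity is None
                else m.fidget_intensity,
                "trial_type": e.trial_type,
                "correct": e.correct,
                "rt_ms": math.nan if e.rt_ms is None else e.rt_ms,
            }
        )
    return pd.DataFrame(rows)


def combine_sensors(arm: FidgetMetrics, leg: FidgetMetrics) -> FidgetMetrics:
    """Sum all three variables across sensors (the arm + leg convention).

    Undefined values are skipped; the combination is undefined only when
    both sensors are undefined.  Commutative and associative.
    """
    return combine_axes([arm, leg])


def combine_sensor_tables(arm: pd.DataFrame, leg: pd.DataFrame) -> pd.DataFrame:
    """Row-wise arm + leg combination of two per-trial metric tables."""
    if not arm["trial_index"].equals(leg["trial_index"]):
        raise ValueError("sensor tables cover different trials")
    out = arm.copy()
    out["sensor_site"] = "arm+leg"
    for col in METRIC_COLUMNS:
        a, b = arm[col].to_numpy(), leg[col].to_numpy()
        both_nan = np.isnan(a) & np.isnan(b)
        summed = np.nansum(np.column_stack([a, b]), axis=1)
        summed[both_nan] = np.nan
        out[col] = summed
    return out


def aggregate_metrics(
    table: pd.DataFrame, subset: pd.Series | np.ndarray | None = None
) -> pd.DataFrame:
    """Mean and SD of each fidget variable over the selected trials.

    Undefined (NaN) values are skipped; the count of contributing trials
    is reported per variable.  SD is the sample standard deviation.
    """
    sel = table if subset is None else table.loc[np.asarray(subset, dtype=bool)]
    if len(sel) == 0:
        raise ValueError("subset selects no trials")
    rows = []
    for col in METRIC_COLUMNS:
        vals = sel[col].dropna()
        rows.append(
            {
                "variable": col,
                "mean": float(vals.mean()) if len(vals) else math.nan,
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0 if len(vals) == 1 else math.nan,
                "n_trials": int(len(vals)),
            }
        )
    return pd.DataFrame(rows).set_index("variable")
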