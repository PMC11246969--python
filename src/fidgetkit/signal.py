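"""Raw recordings to band-limited movement: derivative, FFT band selection,
inverse FFT reconstruction.

The derivative is a forward first difference scaled by the sampling
interval, so the movement signal is one sample shorter than the recording.
Band reconstruction applies a plain FFT -> zero-out-of-band -> inverse FFT
with no windowing; spectral leakage at epoch edges is accepted.  Filtering
is intended for the whole-session signal, which is then epoched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AXES = ("x", "y", "z")


@dataclass(frozen=True)
class FrequencyBand:
    """Closed frequency interval [low_hz, high_hz] retained by the filter.

    The default band (1, 20) excludes the DC bin; with ``low_hz = 0`` DC
    is retained.
    """

    low_hz: float = 1.0
    high_hz: float = 20.0

    def __post_init__(self) -> None:
        if self.low_hz < 0:
            raise ValueError("low_hz must be >= 0")
        if self.high_hz <= self.low_hz:
            raise ValueError("high_hz must exceed low_hz")


@dataclass(frozen=True)
class AccelerometerRecording:
    """Uniformly sampled 3-axis position samples from one sensor site."""

    sensor_site: str
    sample_rate_hz: float
    samples: np.ndarray  # shape (n, 3), device units
    start_time_ms: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2 or samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if samples.shape[0] < 2:
            raise ValueError("recording needs at least 2 samples")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def axis(self, name: str) -> np.ndarray:
        return self.samples[:, AXES.index(name)]


@dataclass(frozen=True)
class MovementSignal:
    """Per-axis movement values: first difference scaled by the sample
    interval.  Sample ``i`` carries the time of recording sample ``i``."""

    sensor_site: str
    sample_rate_hz: float
    values: np.ndarray  # shape (n, 3)
    start_time_ms: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != 3:
            raise ValueError("values must have shape (n, 3)")
        if not np.all(np.isfinite(values)):
            raise ValueError("movement values must be finite")
        object.__setattr__(self, "values", values)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def nyquist_hz(self) -> float:
        return self.sample_rate_hz / 2.0

    def times_ms(self) -> np.ndarray:
        step = 1000.0 / self.sample_rate_hz
        return self.start_time_ms + np.arange(self.n_samples) * step

    def axis(self, name: str) -> np.ndarray:
        return self.values[:, AXES.index(name)]


def differentiate(recording: AccelerometerRecording) -> MovementSignal:
    """Per-axis forward first difference divided by the sample interval.

    Output is one sample shorter than the recording; site, rate and clock
    offset are preserved.
    """
    diffs = np.diff(recording.samples, axis=0) * recording.sample_rate_hz
    return MovementSignal(
        sensor_site=recording.sensor_site,
        sample_rate_hz=recording.sample_rate_hz,
        values=diffs,
        start_time_ms=recording.start_time_ms,
    )


def band_reconstruct(movement: MovementSignal, band: FrequencyBand) -> MovementSignal:
    """Zero every FFT bin strictly outside [low, high] and invert.

    The mask is applied to the one-sided (rfft) spectrum, which enforces
    Hermitian symmetry, so the reconstruction is exactly real.  Bins with
    frequency in the closed interval are kept.  Output length equals
    input length.
    """
    if band.high_hz > movement.nyquist_hz:
        raise ValueError(
            f"band high {band.high_hz} Hz exceeds Nyquist {movement.nyquist_hz} Hz"
        )
    n = movement.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / movement.sample_rate_hz)
    keep = (freqs >= band.low_hz) & (freqs <= band.high_hz)
    spectra = np.fft.rfft(movement.values, axis=0)
    spectra[~keep, :] = 0.0
    out = np.fft.irfft(spectra, n=n, axis=0)
    return MovementSignal(
        sensor_site=movement.sensor_site,
        sample_rate_hz=movement.sample_rate_hz,
        values=out,
        start_time_ms=movement.start_time_ms,
    )


def spectrum(movement: MovementSignal) -> dict[str, np.ndarray]:
    """One-sided energy-preserving magnitude spectrum per axis.

    Returns ``{"frequency_hz": f, "x": m, "y": m, "z": m}`` with
    frequencies 0..Nyquist.  Magnitudes are scaled so that the sum of
    squared magnitudes over bins equals the time-domain energy
    ``sum(v**2)`` (Parseval).
    """
    n = movement.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / movement.sample_rate_hz)
    spectra = np.fft.rfft(movement.values, axis=0)
    # weights fold the negative-frequency half into interior bins; DC and
    # (for even n) the Nyquist bin appear once in the full spectrum
    weights = np.full(freqs.shape, 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    mags = np.abs(spectra) * np.sqrt(weights[:, None] / n)
    out = {"frequency_hz": freqs}
    for i, ax in enumerate(AXES):
        out[ax] = mags[:, i]
    return out
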