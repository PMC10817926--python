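"""Uniformly sampled waveform segments and their plain-text file dialect.

A segment file is two-column delimited text (``time_s,value``) with a header
row; the sampling rate is implied by the time column and validated on load.
This is the interchange format between the simulator and the preprocessing
stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

CHANNELS = ("ABP", "CO", "HR")


class WaveformLoadError(ValueError):
    """Raised when a segment file is missing, malformed or non-uniform."""


@dataclass
class WaveformSegment:
    """One channel's uniformly sampled values.

    Attributes
    ----------
    samples : ndarray
        Sample values (mmHg for ABP, L/min for CO, bpm for HR).
    sample_rate_hz : float
        Sampling rate; 1000 or 100 Hz in the standard pipeline.
    start_time_s : float
        Time of the first sample, seconds.
    channel : str
        One of ``ABP``, ``CO``, ``HR``.
    """

    samples: np.ndarray
    sample_rate_hz: float
    start_time_s: float = 0.0
    channel: str = "ABP"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain missing or non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def times(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_samples) / self.sample_rate_hz

    def with_samples(self, samples, sample_rate_hz=None) -> "WaveformSegment":
        return replace(
            self,
            samples=np.asarray(samples, dtype=float),
            sample_rate_hz=sample_rate_hz or self.sample_rate_hz,
        )


def save_segment(seg: WaveformSegment, path) -> None:
    """Write a segment as two-column delimited text (time_s, value)."""
    path = Path(path)
    data = np.column_stack([seg.times, seg.samples])
    header = "time_s,value"
    np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.6f")


def load_segment(path, channel: str = "ABP", expected_rate_hz: float | None = None,
                 rate_tolerance: float = 0.01) -> WaveformSegment:
    """Load a two-column delimited text file as a :class:`WaveformSegment`.

    Validates uniform sampling: the maximum inter-sample interval deviation
    must be below ``rate_tolerance`` (1%) of the sampling period.

    Raises
    ------
    WaveformLoadError
        If the file is missing, empty, non-numeric, or non-uniformly sampled,
        or the inferred rate disagrees with ``expected_rate_hz``.
    """
    path = Path(path)
    if not path.exists():
        raise WaveformLoadError(f"no such waveform file: {path}")
    try:
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    except ValueError as exc:
        raise WaveformLoadError(f"non-numeric rows in {path}: {exc}") from exc
    if data.size == 0:
        raise WaveformLoadError(f"empty waveform file: {path}")
    if data.shape[1] != 2:
        raise WaveformLoadError(f"expected two columns in {path}, got {data.shape[1]}")
    t, v = data[:, 0], data[:, 1]
    if t.size < 2:
        raise WaveformLoadError(f"fewer than two samples in {path}")
    dt = np.diff(t)
    period = np.median(dt)
    if period <= 0:
        raise WaveformLoadError(f"non-increasing time column in {path}")
    if np.max(np.abs(dt - period)) > rate_tolerance * period:
        raise WaveformLoadError(f"non-uniform sampling in {path}")
    rate = 1.0 / period
    if expected_rate_hz is not None and abs(rate - expected_rate_hz) > rate_tolerance * expected_rate_hz:
        raise WaveformLoadError(
            f"rate mismatch in {path}: inferred {rate:.3f} Hz, expected {expected_rate_hz} Hz"
        )
    return WaveformSegment(samples=v, sample_rate_hz=round(rate, 6),
                           start_time_s=float(t[0]), channel=channel)
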