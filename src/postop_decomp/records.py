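"""Core waveform containers.

A :class:`WaveformRecord` is a uniformly sampled single-channel series
(ECG in mV, arterial blood pressure in mmHg, pulse plethysmography in
arbitrary units) together with its sampling rate and the timestamp of the
first sample.  All downstream stages (filtering, windowing, taut-string
approximation, wavelet features) operate on these records.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DataError

CHANNELS = ("ECG", "ABP", "PPG")


@dataclass(frozen=True)
class WaveformRecord:
    """One channel of one subject.

    Parameters
    ----------
    subject_id:
        Opaque subject identifier.
    channel:
        One of ``"ECG"``, ``"ABP"``, ``"PPG"``.
    samples:
        1-D float array of samples.
    fs:
        Sampling rate in Hz, strictly positive.
    t0:
        Time of the first sample in seconds (an arbitrary but per-subject
        consistent clock).
    """

    subject_id: str
    channel: str
    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise DataError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        if not self.fs > 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise DataError("samples must be a 1-D series")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration_s

    def with_samples(self, samples: np.ndarray, t0: float | None = None) -> "WaveformRecord":
        return replace(self, samples=np.asarray(samples, dtype=float),
                       t0=self.t0 if t0 is None else t0)


@dataclass(frozen=True)
class BandSpec:
    """Butterworth band-pass specification (order, low and high cutoffs in Hz)."""

    order: int
    low_hz: float
    high_hz: float

    def __post_init__(self):
        if not (0 < self.low_hz < self.high_hz):
            raise DataError(f"need 0 < low_hz < high_hz, got {self.low_hz}, {self.high_hz}")
        if self.order < 1:
            raise DataError("filter order must be >= 1")


@dataclass(frozen=True)
class HrvSeries:
    """Heart-rate-variability series: successive R-R intervals in seconds."""

    intervals: np.ndarray
    peak_indices: np.ndarray
    fs: float

    def __post_init__(self):
        object.__setattr__(self, "intervals", np.asarray(self.intervals, dtype=float))
        object.__setattr__(self, "peak_indices", np.asarray(self.peak_indices, dtype=np.int64))
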