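"""Waveform preprocessing: band-pass filtering, tumbling windows, R-peaks, HRV.

Artifact removal follows the channel-specific Butterworth bands used for
bedside-monitor data: ECG order 2, 0.5-40 Hz; ABP order 3, 1.25-25 Hz;
PPG order 3, 1.75-10 Hz.  Filters are applied zero-phase (forward-backward)
so that waveform morphology, which the taut-string features summarise, is
not skewed by phase distortion.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, DataError, IncompleteSignal
from .records import BandSpec, HrvSeries, WaveformRecord

#: channel -> default Butterworth band
DEFAULT_BANDS = {
    "ECG": BandSpec(order=2, low_hz=0.5, high_hz=40.0),
    "ABP": BandSpec(order=3, low_hz=1.25, high_hz=25.0),
    "PPG": BandSpec(order=3, low_hz=1.75, high_hz=10.0),
}

#: typical bedside-monitor sampling rates, used by the synthetic generator
DEFAULT_SAMPLING_HZ = {"ECG": 240.0, "ABP": 120.0, "PPG": 120.0}


def bandpass_filter(record: WaveformRecord, spec: BandSpec | None = None) -> WaveformRecord:
    """Zero-phase Butterworth band-pass of one waveform channel.

    When ``spec`` is omitted the channel-appropriate default band is used.
    Raises :class:`ConfigError` if the band does not fit under the Nyquist
    frequency and :class:`DataError` for non-finite samples.
    """
    if spec is None:
        spec = DEFAULT_BANDS[record.channel]
    nyq = record.fs / 2.0
    if spec.high_hz >= nyq:
        raise ConfigError(
            f"band [{spec.low_hz}, {spec.high_hz}] Hz does not fit below the "
            f"Nyquist frequency {nyq} Hz of {record.channel} at fs={record.fs}"
        )
    x = record.samples
    if not np.all(np.isfinite(x)):
        raise DataError(f"{record.channel} samples contain non-finite values")
    if x.size < 3 * spec.order:
        raise DataError("record too short for the requested filter order")
    sos = sps.butter(spec.order, [spec.low_hz, spec.high_hz], btype="bandpass",
                     fs=record.fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    return record.with_samples(y)


def butterworth_gain(spec: BandSpec, freq_hz: float, fs: float) -> float:
    """Magnitude response of the (two-pass) band-pass at one frequency.

    Exposed so tests can use the analytic response as an oracle.  The
    forward-backward application squares the single-pass magnitude.
    """
    sos = sps.butter(spec.order, [spec.low_hz, spec.high_hz], btype="bandpass",
                     fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=[freq_hz], fs=fs)
    return float(np.abs(h[0]) ** 2)


def segment_tumbling_windows(record: WaveformRecord, window_minutes: float = 3.0,
                             n_windows: int = 5) -> list[WaveformRecord]:
    """Split the trailing span of a record into non-overlapping tumbling windows.

    Returns exactly ``n_windows`` contiguous windows of
    ``window_minutes * 60 * fs`` samples each, ending at the record's end
    (the analysis span is anchored to the end of the record, i.e. closest to
    the prediction gap).  A record shorter than the required span is a
    :class:`DataError`.
    """
    win_len = int(round(window_minutes * 60.0 * record.fs))
    if win_len < 1:
        raise DataError("window length must span at least one sample")
    needed = win_len * n_windows
    if record.n_samples < needed:
        raise DataError(
            f"record spans {record.n_samples} samples "
            f"({record.n_samples / record.fs:.1f} s) but {needed} samples "
            f"({needed / record.fs:.1f} s) are required for "
            f"{n_windows} x {window_minutes} min windows"
        )
    start = record.n_samples - needed
    out = []
    for w in range(n_windows):
        a = start + w * win_len
        b = a + win_len
        out.append(record.with_samples(record.samples[a:b], t0=record.t0 + a / record.fs))
    return out


def detect_r_peaks(ecg_window: WaveformRecord, *,
                   refractory_s: float = 0.2,
                   smooth_s: float = 0.12,
                   threshold_frac: float = 0.5,
                   block_s: float = 2.0,
                   percentile: float = 95.0) -> np.ndarray:
    """Detect R-peaks in a filtered ECG window.

    A moving-window local-maximum detector on the squared, differenced ECG
    with an adaptive threshold (``threshold_frac`` times the rolling
    ``percentile``-th percentile of the detection signal over ``block_s``
    blocks) and a ``refractory_s`` refractory period.  Peak locations are
    refined to the local maximum of the ECG itself.

    Returns strictly increasing sample indices.  Raises
    :class:`IncompleteSignal` when fewer than two peaks are found, which is
    the subject-exclusion path.
    """
    x = ecg_window.samples
    fs = ecg_window.fs
    if x.size < 4 or float(np.ptp(x)) == 0.0:
        raise IncompleteSignal("ECG window flat or too short for peak detection")

    # slope-emphasised energy signal
    d = np.diff(x, prepend=x[0])
    e = d * d
    k = max(1, int(round(smooth_s * fs)))
    e = np.convolve(e, np.ones(k) / k, mode="same")

    # adaptive threshold per non-overlapping block
    blk = max(1, int(round(block_s * fs)))
    thr = np.empty_like(e)
    for a in range(0, e.size, blk):
        b = min(a + blk, e.size)
        thr[a:b] = threshold_frac * np.percentile(e[a:b], percentile)
    dist = max(1, int(round(refractory_s * fs)))
    peaks, _ = sps.find_peaks(e, distance=dist, height=thr)
    if peaks.size < 2:
        raise IncompleteSignal("fewer than 2 R-peaks detected in window")

    # refine to the ECG local maximum near each energy peak
    half = max(1, int(round(0.05 * fs)))
    refined = []
    for p in peaks:
        a, b = max(0, p - half), min(x.size, p + half + 1)
        refined.append(a + int(np.argmax(x[a:b])))
    refined = np.unique(np.asarray(refined, dtype=np.int64))
    # enforce refractory after refinement
    keep = [int(refined[0])]
    for p in refined[1:]:
        if p - keep[-1] >= dist:
            keep.append(int(p))
        elif x[p] > x[keep[-1]]:
            keep[-1] = int(p)
    peaks = np.asarray(keep, dtype=np.int64)
    if peaks.size < 2:
        raise IncompleteSignal("fewer than 2 R-peaks detected in window")
    return peaks


def compute_hrv(peak_indices: np.ndarray, fs: float) -> HrvSeries:
    """Successive peak-to-peak durations (seconds) from R-peak sample indices."""
    peaks = np.asarray(peak_indices, dtype=np.int64)
    if peaks.size < 2:
        raise IncompleteSignal("need at least 2 peaks to form an HRV series")
    if np.any(np.diff(peaks) <= 0):
        raise DataError("peak indices must be strictly increasing")
    intervals = np.diff(peaks) / float(fs)
    return HrvSeries(intervals=intervals, peak_indices=peaks, fs=fs)
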