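"""Filtering, tumbling windows, R-peak detection and HRV."""

import numpy as np
import pytest

from postop_decomp import (CohortSpec, WaveformRecord,
                           bandpass_filter, compute_hrv, detect_r_peaks,
                           generate_cohort, segment_tumbling_windows)
from postop_decomp.errors import ConfigError, DataError, IncompleteSignal
from postop_decomp.preprocessing import DEFAULT_BANDS, butterworth_gain


def _ecg(samples, fs=240.0):
    return WaveformRecord(subject_id="s", channel="ECG", samples=samples, fs=fs)


class TestBandpass:
    def test_zero_signal_stays_zero(self):
        out = bandpass_filter(_ecg(np.zeros(5000)))
        assert np.allclose(out.samples, 0.0)

    def test_subband_drift_attenuated_per_analytic_response(self):
        fs, f0 = 240.0, 0.05
        t = np.arange(int(120 * fs)) / fs
        x = np.sin(2 * np.pi * f0 * t)
        out = bandpass_filter(_ecg(x, fs))
        # discard filtfilt edge transients of the very slow tone
        core = slice(int(20 * fs), -int(20 * fs))
        rms_ratio = np.std(out.samples[core]) / np.std(x[core])
        gain = butterworth_gain(DEFAULT_BANDS["ECG"], f0, fs)
        assert rms_ratio <= gain * 1.5  # at least the analytic attenuation
        assert rms_ratio < 0.05

    def test_passband_tone_preserved(self):
        fs = 240.0
        t = np.arange(int(30 * fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        out = bandpass_filter(_ecg(x, fs))
        assert np.std(out.samples) == pytest.approx(np.std(x), rel=0.05)

    def test_filtering_idempotent_in_passband(self):
        fs = 240.0
        t = np.arange(int(30 * fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        once = bandpass_filter(_ecg(x, fs))
        twice = bandpass_filter(once)
        assert np.std(twice.samples) == pytest.approx(np.std(once.samples), rel=0.05)

    def test_band_above_nyquist_is_config_error(self):
        with pytest.raises(ConfigError):
            bandpass_filter(_ecg(np.zeros(1000), fs=60.0))  # ECG band needs fs > 80

    def test_nonfinite_samples_rejected(self):
        x = np.zeros(1000)
        x[5] = np.nan
        with pytest.raises(DataError):
            bandpass_filter(_ecg(x))


class TestTumblingWindows:
    def test_fifteen_minutes_gives_five_windows(self):
        rec = _ecg(np.arange(15 * 60 * 240, dtype=float))
        wins = segment_tumbling_windows(rec)
        assert len(wins) == 5
        assert all(w.n_samples == 3 * 60 * 240 for w in wins)

    def test_fourteen_minutes_is_a_data_error(self):
        rec = _ecg(np.zeros(14 * 60 * 240))
        with pytest.raises(DataError, match="required"):
            segment_tumbling_windows(rec)

    def test_windows_partition_the_trailing_span_exactly(self):
        rng = np.random.default_rng(0)
        rec = _ecg(rng.normal(0, 1, 16 * 60 * 240))  # 16 min: 1 min of slack
        wins = segment_tumbling_windows(rec)
        cat = np.concatenate([w.samples for w in wins])
        assert np.array_equal(cat, rec.samples[-cat.size:])
        # contiguity of timestamps
        for a, b in zip(wins, wins[1:]):
            assert b.t0 == pytest.approx(a.t0 + a.duration_s)


class TestPeakDetection:
    def test_impulse_train_detected_exactly(self):
        fs = 240.0
        x = np.zeros(int(30 * fs))
        truth = np.arange(int(fs), x.size - int(fs), int(fs))
        x[truth] = 1.0
        peaks = detect_r_peaks(_ecg(x, fs))
        assert np.array_equal(peaks, truth)

    def test_constant_signal_flags_incomplete(self):
        with pytest.raises(IncompleteSignal):
            detect_r_peaks(_ecg(np.ones(5000)))

    def test_synthetic_ecg_recall_and_precision(self):
        # one generated subject at SNR 10 dB; every window must reach
        # precision/recall >= 0.95 against the generator's true beat times
        spec = CohortSpec(n_subjects=4, incidence=0.5, seed=5, snr_db=10.0,
                          cohort_id="pk")
        cohort = generate_cohort(spec)
        subj = cohort.subject(0)
        rec = bandpass_filter(subj.waveforms["ECG"])
        wins = segment_tumbling_windows(rec)
        for w in wins:
            peaks = detect_r_peaks(w)
            det_t = w.t0 + peaks / w.fs
            truth = subj.true_peak_times
            truth_w = truth[(truth >= w.t0) & (truth < w.t0 + w.duration_s)]
            tol = 0.02
            recall = np.mean([np.min(np.abs(det_t - t)) < tol for t in truth_w])
            precision = np.mean([np.min(np.abs(truth_w - t)) < tol for t in det_t])
            assert recall >= 0.95 and precision >= 0.95

    def test_sixty_bpm_synthetic_count_and_accuracy(self):
        fs = 240.0
        t = np.arange(int(180 * fs)) / fs
        truth = np.arange(0.5, 179.5, 1.0)  # exactly 60 bpm
        x = np.zeros_like(t)
        for bt in truth:
            x += np.exp(-0.5 * ((t - bt) / 0.012) ** 2)
        x += np.random.default_rng(0).normal(0, 0.03, x.size)
        peaks = detect_r_peaks(_ecg(x, fs))
        assert abs(peaks.size - truth.size) <= 1
        det_t = peaks / fs
        matched = [np.min(np.abs(det_t - bt)) < 0.02 for bt in truth]
        assert np.mean(matched) > 0.99


class TestHrv:
    def test_uniform_peaks_give_unit_intervals(self):
        hrv = compute_hrv(np.array([0, 240, 480]), fs=240.0)
        assert np.allclose(hrv.intervals, 1.0)
        assert hrv.intervals.size == 2

    def test_single_peak_flags_incomplete(self):
        with pytest.raises(IncompleteSignal):
            compute_hrv(np.array([100]), fs=240.0)

    def test_generator_ground_truth_roundtrip(self):
        # quantizing the true beat times to the sample grid and differencing
        # reproduces the true inter-beat gaps to within one sample
        spec = CohortSpec(n_subjects=4, incidence=0.5, seed=9, cohort_id="h")
        subj = generate_cohort(spec).subject(1)
        fs = spec.fs_ecg
        idx = np.round(subj.true_peak_times * fs).astype(int)
        hrv = compute_hrv(idx, fs)
        assert np.max(np.abs(hrv.intervals - subj.true_intervals)) <= 1.0 / fs
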