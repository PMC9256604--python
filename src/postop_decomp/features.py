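"""Per-window, per-epsilon feature families and the 5,150-feature set.

For every tumbling window and every epsilon in the per-channel grid the
pipeline computes:

* ``ECG``  - 6 morphological summaries of the taut-string estimate of ECG;
* ``HRV``  - the same 6 summaries of the taut-string estimate of the R-R
  interval series;
* ``DTCWPT`` - 152 statistics of the level-2 dual-tree complex wavelet
  packet coefficients of the taut-string estimate of ECG;
* ``ABP`` / ``PPG`` - 21 distributional summaries each of the taut-string
  estimate, its first and its second differences.

With 5 epsilons, 5 windows and 6+6+152+21+21 = 206 features per
(epsilon, window) cell this yields 25 x 206 = 5,150 scalars per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dtcwpt import QShiftFilterBank, design_qshift_filterbank, dtcwpt_decompose
from .errors import DataError, SubjectExcluded, IncompleteSignal
from .preprocessing import compute_hrv, detect_r_peaks
from .records import WaveformRecord
from .taut_string import TautStringEstimate, taut_string_estimate

FEATURE_TYPES = ("ECG", "HRV", "DTCWPT", "ABP", "PPG")
N_FEATURES = {"ECG": 6, "HRV": 6, "DTCWPT": 152, "ABP": 21, "PPG": 21}


@dataclass(frozen=True)
class EpsilonGrid:
    """Tube half-widths per feature type (5 strictly increasing values each)."""

    ecg: tuple = (0.0100, 0.1575, 0.3050, 0.4525, 0.6000)
    hrv: tuple = (0.0010, 0.0258, 0.0505, 0.0753, 0.1000)
    dtcwpt: tuple = (0.0100, 0.1575, 0.3050, 0.4525, 0.6000)
    abp: tuple = (0.1000, 0.7000, 1.3000, 1.9000, 2.5000)
    ppg: tuple = (1.0000, 8.7500, 16.5000, 24.2500, 32.0000)

    def __post_init__(self):
        for name in ("ecg", "hrv", "dtcwpt", "abp", "ppg"):
            vals = getattr(self, name)
            if len(vals) != 5 or any(b <= a for a, b in zip(vals, vals[1:])):
                raise DataError(f"epsilon grid for {name} must be 5 strictly increasing values")

    def for_type(self, ftype: str) -> tuple:
        return getattr(self, ftype.lower())


@dataclass
class FeatureSet:
    """All signal features of one subject.

    ``arrays[type]`` has shape ``(n_epsilon=5, n_features, n_windows=5)``;
    ``names[type]`` aligns with the feature axis.
    """

    subject_id: str
    arrays: dict[str, np.ndarray]
    names: dict[str, list[str]] = field(default_factory=dict)

    @property
    def total_scalars(self) -> int:
        return int(sum(a.size for a in self.arrays.values()))


# ---------------------------------------------------------------------------
# taut-string morphology

_SMALL6 = ("seg_count", "slope_mean", "slope_sd", "seglen_mean", "seglen_sd", "total_variation")

_STAT7 = ("mean", "sd", "median", "min", "max", "skew", "kurtosis")
_LARGE21 = tuple(f"{series}_{s}" for series in ("g", "dg", "d2g") for s in _STAT7)


def _moments7(x: np.ndarray) -> np.ndarray:
    if x.size == 0:
        return np.zeros(7)
    m = float(np.mean(x))
    z = x - m
    s2 = float(np.mean(z * z))
    sd = np.sqrt(s2)
    scale = float(np.max(np.abs(x)))
    if sd <= 1e-10 * max(scale, 1.0):
        # (near-)constant series: higher moments are numerically meaningless
        skew = kurt = 0.0
    else:
        z2 = z * z
        skew = float(np.mean(z2 * z)) / s2 ** 1.5
        kurt = float(np.mean(z2 * z2)) / (s2 * s2) - 3.0  # excess kurtosis
    return np.array([m, sd, np.median(x), np.min(x), np.max(x), skew, kurt])


def ts_morphological_features(est: TautStringEstimate, family: str) -> np.ndarray:
    """Morphological summary of a taut-string estimate.

    ``family="small6"`` (ECG, HRV): segment count, mean/SD of segment
    slopes, mean/SD of segment lengths (samples), and total variation of g.
    ``family="large21"``: 7 distributional statistics of each of g, diff(g)
    and the second differences of g.
    """
    if est.n < 3:
        raise DataError("degenerate taut-string estimate (length < 3)")
    if family == "small6":
        slopes = est.seg_slopes
        lengths = est.seg_lengths
        tv = float(np.abs(np.diff(est.g)).sum())
        out = np.array([slopes.size, slopes.mean(), slopes.std(),
                        lengths.mean(), lengths.std(), tv])
    elif family == "large21":
        g = est.g
        out = np.concatenate([_moments7(g), _moments7(np.diff(g)), _moments7(np.diff(g, 2))])
    else:
        raise DataError(f"unknown feature family {family!r}")
    if not np.all(np.isfinite(out)):
        raise DataError("non-finite morphological feature")
    return out


# ---------------------------------------------------------------------------
# DTCWPT statistics

_STAT19 = ("mean", "sd", "median", "min", "max", "iqr", "mad", "skew", "kurtosis",
           "energy", "rms", "entropy", "zero_crossings", "total_variation",
           "max_abs", "p5", "p95", "mean_abs", "n_above_rms")


def _stats19(x: np.ndarray) -> np.ndarray:
    e = float(x @ x)
    rms = np.sqrt(e / x.size)
    if e > 0.0:
        p = x * x / e
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = float(-np.sum(np.where(p > 0, p * np.log(p), 0.0)))
    else:
        ent = 0.0  # all-zero subband guard
    m7 = _moments7(x)
    q5, q25, med, q75, q95 = np.percentile(x, [5, 25, 50, 75, 95])
    return np.array([
        m7[0], m7[1], m7[2], m7[3], m7[4],
        q75 - q25,
        float(np.median(np.abs(x - med))),
        m7[5], m7[6],
        e, rms, ent,
        float(np.count_nonzero(np.diff(np.signbit(x)))),
        float(np.abs(np.diff(x)).sum()),
        float(np.max(np.abs(x))),
        q5, q95,
        float(np.mean(np.abs(x))),
        float(np.count_nonzero(np.abs(x) > rms)),
    ])


def dtcwpt_features(ts_ecg: TautStringEstimate, fb: QShiftFilterBank | None = None) -> np.ndarray:
    """152 statistics of the level-2 DTCWPT of a taut-string ECG estimate.

    The 4 complex subbands give 8 real sequences (real and imaginary
    parts); 19 statistics of each yield 8 x 19 = 152 values.  The energy
    entries of the 4 real-part sequences sum to the tree-1 coefficient
    energy, i.e. to the energy of the analysed signal.
    """
    if fb is None:
        fb = design_qshift_filterbank(2)
    sb = dtcwpt_decompose(ts_ecg.g, fb, k=2)
    parts = []
    for band in sb.complex_subbands:
        parts.append(np.real(band))
    for band in sb.complex_subbands:
        parts.append(np.imag(band))
    out = np.concatenate([_stats19(p) for p in parts])
    if out.size != N_FEATURES["DTCWPT"]:
        raise AssertionError("DTCWPT feature count mismatch")
    return out


def dtcwpt_feature_names() -> list[str]:
    names = []
    for part in ("re", "im"):
        for band in range(4):
            for s in _STAT19:
                names.append(f"band{band}.{part}.{s}")
    return names


# ---------------------------------------------------------------------------
# assembling the per-subject set


def feature_names(ftype: str) -> list[str]:
    if ftype in ("ECG", "HRV"):
        return list(_SMALL6)
    if ftype in ("ABP", "PPG"):
        return list(_LARGE21)
    return dtcwpt_feature_names()


def scalar_names(grid: EpsilonGrid | None = None) -> list[str]:
    """Stable names for all 5,150 scalars: ``{type}.eps{j}.win{w}.{stat}``."""
    out = []
    for ftype in FEATURE_TYPES:
        base = feature_names(ftype)
        for j in range(5):
            for w in range(5):
                for stat in base:
                    out.append(f"{ftype}.eps{j}.win{w}.{stat}")
    return out


def extract_all_features(ecg_windows: list[WaveformRecord],
                         abp_windows: list[WaveformRecord],
                         ppg_windows: list[WaveformRecord],
                         grid: EpsilonGrid | None = None,
                         fb: QShiftFilterBank | None = None,
                         subject_id: str = "") -> FeatureSet:
    """Compute the full (epsilon x feature x window) set for one subject.

    Expects filtered, windowed records (5 windows per channel).  HRV is
    derived from the ECG windows here so that a window with undetectable
    R-peaks can surface as a subject-level exclusion.  Raises
    :class:`SubjectExcluded` when any channel/window is missing or
    incomplete.
    """
    grid = grid or EpsilonGrid()
    fb = fb or design_qshift_filterbank(2)
    n_win = 5
    for name, wins in (("ECG", ecg_windows), ("ABP", abp_windows), ("PPG", ppg_windows)):
        if wins is None or len(wins) != n_win:
            raise SubjectExcluded(f"subject {subject_id!r}: missing/incomplete {name} windows")

    arrays = {t: np.empty((5, N_FEATURES[t], n_win)) for t in FEATURE_TYPES}
    try:
        for w in range(n_win):
            ecg = ecg_windows[w].samples
            peaks = detect_r_peaks(ecg_windows[w])
            hrv = compute_hrv(peaks, ecg_windows[w].fs)
            if hrv.intervals.size < 3:
                raise IncompleteSignal("too few R-R intervals for taut-string features")
            same_grid = grid.dtcwpt == grid.ecg
            for j, eps in enumerate(grid.ecg):
                est = taut_string_estimate(ecg, eps)
                arrays["ECG"][j, :, w] = ts_morphological_features(est, "small6")
                if same_grid:  # default: reuse the estimate for the wavelet family
                    arrays["DTCWPT"][j, :, w] = dtcwpt_features(est, fb)
            if not same_grid:
                for j, eps in enumerate(grid.dtcwpt):
                    est = taut_string_estimate(ecg, eps)
                    arrays["DTCWPT"][j, :, w] = dtcwpt_features(est, fb)
            for j, eps in enumerate(grid.hrv):
                est = taut_string_estimate(hrv.intervals, eps)
                arrays["HRV"][j, :, w] = ts_morphological_features(est, "small6")
            for j, eps in enumerate(grid.abp):
                est = taut_string_estimate(abp_windows[w].samples, eps)
                arrays["ABP"][j, :, w] = ts_morphological_features(est, "large21")
            for j, eps in enumerate(grid.ppg):
                est = taut_string_estimate(ppg_windows[w].samples, eps)
                arrays["PPG"][j, :, w] = ts_morphological_features(est, "large21")
    except IncompleteSignal as exc:
        raise SubjectExcluded(f"subject {subject_id!r}: {exc}") from exc

    return FeatureSet(subject_id=subject_id, arrays=arrays,
                      names={t: feature_names(t) for t in FEATURE_TYPES})
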