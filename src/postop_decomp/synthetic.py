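"""Synthetic surgical cohorts: waveforms, EHR tables and event labels.

Because bedside-monitor cohorts are institutional, the pipeline ships a
generator that emulates their statistical structure end to end: three
cohorts of configurable size and event incidence, 15 minutes of ECG/ABP/PPG
per subject ending one prediction gap before the (real or matched) event
time, and a 542-column EHR table.

Positive subjects drift over the analysis span towards the physiology of
impending hemodynamic decompensation: heart rate rises by ``10 *
effect_size`` bpm by the end of the span, beat-to-beat R-R variability
shrinks to ``1 - 0.5 * effect_size`` of baseline, and ABP/PPG pulse
amplitudes fall to ``1 - 0.3 * effect_size``; a small set of informative
EHR columns (heart rate, lactate, blood pressure, hemoglobin) shifts with
the label.  Negative subjects are stationary.  ``effect_size = 0`` makes
positives and negatives distributionally identical, which is the null
condition used to verify chance-level AUROC.

ECG is a template-beat train (Gaussian P-QRS-T bumps), ABP/PPG are
systolic-upstroke/dicrotic templates phase-locked to the ECG beats, all
with additive white noise at a configured SNR.  The generator emits its
ground truth (true beat times, true R-R intervals, drift magnitude) so
detector and HRV accuracy can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ehr import EhrRecord, EhrSchema, StaticField
from .errors import ArgumentError
from .records import WaveformRecord

# ---------------------------------------------------------------------------
# default EHR schema (542 columns)

_RACE_LEVELS = ("White", "Black", "Asian", "Hispanic", "Other", "Unknown")
_SEX_LEVELS = ("F", "M")
_MED_CATEGORIES = ("PH", "MS", "GA", "HS", "RS")

_COMORBIDITIES = tuple(f"Comorbidity.{name}" for name in (
    "CAD", "CHF", "AFib", "HTN", "DM2", "DM1", "CKD", "ESRD", "COPD", "Asthma",
    "OSA", "PriorMI", "PriorStroke", "PVD", "Cirrhosis", "Obesity", "Anemia",
    "Hypothyroid", "Cancer", "Immunosuppressed", "Smoker", "EtOH", "Dementia",
    "Sepsis", "Arrhythmia", "ValveDisease", "Pacemaker", "Anticoagulated",
    "Dialysis", "Transplant", "GIBleed", "DVT", "PE", "Delirium", "Malnutrition",
    "PulmHTN", "Aneurysm", "Endocarditis", "Myocarditis", "Pericarditis",
    "Cardiomyopathy", "Hyperlipidemia", "Gout", "RheumatoidArthritis", "Lupus",
    "Osteoporosis", "Parkinsons", "Epilepsy", "Depression", "Anxiety",
    "Psychosis", "ChronicPain", "Migraine", "IBD", "Pancreatitis", "Hepatitis",
    "HIV", "TB", "Pneumonia", "UTI", "Cellulitis", "WoundInfection",
    "PressureUlcer", "Frailty", "RecentSurgery", "ReOperation", "Trauma",
    "Burn", "SpinalInjury", "TBI", "Hydrocephalus", "Meningitis", "Scoliosis",
    "HipFracture", "Osteomyelitis", "Amputation", "Bedbound", "HomeO2",
))  # 78 flags

_TEMPORAL = tuple(["HR", "SBP", "DBP", "MAP", "SpO2", "RespRate", "Temp", "CVP",
                   "CardiacIndex", "UrineOutput", "Lactate", "Hgb", "PLT", "WBC",
                   "Sodium", "Potassium", "Chloride", "Bicarbonate", "BUN",
                   "Creatinine", "Glucose", "Calcium", "Magnesium", "Phosphate",
                   "Albumin", "Bilirubin", "AST", "ALT", "INR", "PTT",
                   "Fibrinogen", "Troponin", "BNP", "pH", "PaO2", "PaCO2",
                   "FiO2", "PEEP", "GCS", "RASS", "PainScore", "Intubated",
                   "DailyIntubation", "Milrinone", "NorepiDose"])  # 45 fields

#: features whose level shifts with the deterioration label
_INFORMATIVE = {"HR": +8.0, "Lactate": +1.1, "MAP": -7.0, "SBP": -9.0,
                "Hgb": -0.9, "CardiacIndex": -0.45}

_TEMPORAL_BASE = {"HR": 78.0, "SBP": 118.0, "DBP": 64.0, "MAP": 82.0, "SpO2": 97.0,
                  "RespRate": 16.0, "Temp": 37.0, "CVP": 8.0, "CardiacIndex": 2.6,
                  "UrineOutput": 60.0, "Lactate": 1.4, "Hgb": 10.5, "PLT": 180.0,
                  "WBC": 9.0, "Sodium": 139.0, "Potassium": 4.1, "Chloride": 103.0,
                  "Bicarbonate": 24.0, "BUN": 18.0, "Creatinine": 1.0,
                  "Glucose": 130.0, "Calcium": 8.8, "Magnesium": 2.0,
                  "Phosphate": 3.4, "Albumin": 3.2, "Bilirubin": 0.8, "AST": 35.0,
                  "ALT": 30.0, "INR": 1.2, "PTT": 32.0, "Fibrinogen": 350.0,
                  "Troponin": 0.05, "BNP": 180.0, "pH": 7.38, "PaO2": 95.0,
                  "PaCO2": 40.0, "FiO2": 0.4, "PEEP": 5.0, "GCS": 14.0,
                  "RASS": -1.0, "PainScore": 3.0, "Intubated": 0.0,
                  "DailyIntubation": 0.0, "Milrinone": 0.0, "NorepiDose": 0.02}

_TEMPORAL_SD = {k: max(0.1, abs(v) * 0.12) for k, v in _TEMPORAL_BASE.items()}


def default_ehr_schema() -> EhrSchema:
    """The 542-column default schema used by the synthetic cohorts."""
    static = (StaticField("Age", "numeric"),
              StaticField("Sex", "categorical", _SEX_LEVELS),
              StaticField("Race", "categorical", _RACE_LEVELS),
              *(StaticField(c, "flag") for c in _COMORBIDITIES))
    return EhrSchema(static=static, temporal=_TEMPORAL,
                     med_categories=_MED_CATEGORIES, n_windows=5,
                     temporal_defaults=dict(_TEMPORAL_BASE))


# ---------------------------------------------------------------------------
# specs and containers


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_subjects: int
    incidence: float = 0.174
    effect_size: float = 1.0
    gap_hours: float = 0.5
    seed: int = 0
    heterogeneity: float = 0.0
    cohort_id: str = "cohort"
    fs_ecg: float = 240.0
    fs_abp: float = 120.0
    fs_ppg: float = 120.0
    window_minutes: float = 3.0
    n_windows: int = 5
    snr_db: float = 18.0
    ehr_strength: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.incidence < 1.0):
            raise ArgumentError("incidence must lie in (0, 1)")
        if self.n_subjects < 4:
            raise ArgumentError("a cohort needs at least 4 subjects")
        if self.effect_size < 0:
            raise ArgumentError("effect_size must be >= 0")

    @property
    def span_s(self) -> float:
        return self.window_minutes * 60.0 * self.n_windows


@dataclass
class SyntheticSubject:
    subject_id: str
    label: int
    event_time: float
    waveforms: dict[str, WaveformRecord]
    ehr: EhrRecord
    true_peak_times: np.ndarray
    true_intervals: np.ndarray
    drift_magnitude: float
    window_end_times: np.ndarray


@dataclass
class CohortDataset:
    """Cohort metadata plus a deterministic per-subject factory.

    Waveforms for hundreds of subjects do not fit comfortably in memory,
    so subjects are regenerated on demand from per-subject seeds.
    """

    spec: CohortSpec
    labels: np.ndarray
    subject_ids: list[str]
    _child_seeds: list = field(repr=False, default_factory=list)

    def subject(self, i: int) -> SyntheticSubject:
        rng = np.random.default_rng(self._child_seeds[i])
        return generate_subject(self.spec, int(self.labels[i]), rng,
                                subject_id=self.subject_ids[i])

    def subjects(self):
        for i in range(len(self.subject_ids)):
            yield self.subject(i)

    def __len__(self) -> int:
        return len(self.subject_ids)


# ---------------------------------------------------------------------------
# waveform synthesis

# Gaussian bumps (amplitude, center offset s, width s) of the ECG beat template
_ECG_BUMPS = ((0.12, -0.180, 0.025),   # P
              (-0.15, -0.025, 0.008),  # Q
              (1.00, 0.000, 0.012),    # R
              (-0.20, 0.030, 0.009),   # S
              (0.30, 0.300, 0.060))    # T

_ABP_BUMPS = ((40.0, 0.150, 0.090),    # systolic upstroke
              (8.0, 0.380, 0.070))     # dicrotic wave

_PPG_BUMPS = ((100.0, 0.180, 0.110),
              (25.0, 0.430, 0.090))


def _bump_train(t_grid: np.ndarray, beat_times: np.ndarray, bumps,
                amp_scale: np.ndarray) -> np.ndarray:
    """Sum of per-beat Gaussian bumps, vectorised over a local support."""
    fs = 1.0 / (t_grid[1] - t_grid[0])
    x = np.zeros_like(t_grid)
    t0 = t_grid[0]
    for k, bt in enumerate(beat_times):
        for amp, off, width in bumps:
            c = bt + off
            a = int(max(0, np.floor((c - 4 * width - t0) * fs)))
            b = int(min(t_grid.size, np.ceil((c + 4 * width - t0) * fs) + 1))
            if a >= b:
                continue
            seg = t_grid[a:b] - c
            x[a:b] += amp * amp_scale[k] * np.exp(-0.5 * (seg / width) ** 2)
    return x


def _noise(rng, n, signal_power, snr_db):
    p = signal_power / (10.0 ** (snr_db / 10.0))
    return rng.normal(0.0, np.sqrt(p), n)


def generate_subject(spec: CohortSpec, label: int, rng: np.random.Generator,
                     subject_id: str = "S0") -> SyntheticSubject:
    """One subject: waveforms with planted drift, EHR record, ground truth."""
    span = spec.span_s
    t_end = 0.0 + span  # waveform clock: analysis span is [0, span]
    event_time = t_end + spec.gap_hours * 3600.0
    eff = spec.effect_size if label else 0.0

    # cohort-shift: subject-level baselines widen with heterogeneity
    het = spec.heterogeneity
    hr0 = rng.normal(76.0 + 6.0 * het * rng.standard_normal(), 5.0)
    hr0 = float(np.clip(hr0, 50.0, 110.0))
    rr_sd0 = float(np.clip(rng.normal(0.045, 0.008), 0.015, 0.09))
    amp_wander_sd = 0.05 * (1 + het)

    # beat times: ramped tachycardia + shrinking R-R jitter for positives
    beats = [rng.uniform(0.0, 0.8)]
    while beats[-1] < span + 1.0:
        frac = min(1.0, beats[-1] / span)
        hr_t = hr0 + eff * 10.0 * frac
        sd_t = rr_sd0 * (1.0 - 0.5 * eff * frac)
        rr = 60.0 / hr_t + rng.normal(0.0, sd_t)
        rr = max(0.30, rr)
        beats.append(beats[-1] + rr)
    beats = np.asarray(beats)
    in_span = beats[(beats >= 0.0) & (beats <= span)]
    frac = np.minimum(1.0, beats / span)
    pulse_scale = 1.0 - 0.3 * eff * frac  # blunted pulse amplitude
    ecg_scale = 1.0 + rng.normal(0.0, amp_wander_sd, beats.size)

    waveforms = {}
    for channel, fs, bumps, baseline, scale in (
            ("ECG", spec.fs_ecg, _ECG_BUMPS, 0.0, ecg_scale),
            ("ABP", spec.fs_abp, _ABP_BUMPS, 72.0, pulse_scale),
            ("PPG", spec.fs_ppg, _PPG_BUMPS, 0.0, pulse_scale)):
        n = int(round(span * fs))
        t_grid = np.arange(n) / fs
        x = baseline + _bump_train(t_grid, beats, bumps, scale)
        x += _noise(rng, n, np.var(x), spec.snr_db)
        waveforms[channel] = WaveformRecord(subject_id=subject_id, channel=channel,
                                            samples=x, fs=fs, t0=0.0)

    window_ends = (np.arange(1, spec.n_windows + 1) * spec.window_minutes * 60.0)

    ehr = _generate_ehr(spec, label, rng, subject_id, window_ends)
    return SyntheticSubject(
        subject_id=subject_id, label=int(label), event_time=event_time,
        waveforms=waveforms, ehr=ehr,
        true_peak_times=in_span, true_intervals=np.diff(in_span),
        drift_magnitude=eff, window_end_times=window_ends)


def _generate_ehr(spec: CohortSpec, label: int, rng, subject_id, window_ends):
    schema = default_ehr_schema()
    shift = spec.ehr_strength * spec.effect_size if label else 0.0
    static = {"Age": float(np.round(np.clip(rng.normal(63, 11), 18, 95))),
              "Sex": _SEX_LEVELS[rng.integers(2)],
              "Race": _RACE_LEVELS[min(int(rng.geometric(0.45)) - 1, 5)]}
    base_p = 0.12 + 0.05 * spec.heterogeneity
    for i, c in enumerate(_COMORBIDITIES):
        p = np.clip(base_p + (0.08 * shift if i < 8 else 0.0), 0.01, 0.9)
        static[c] = int(rng.random() < p)
    med = {c: int(rng.poisson(2.0 + (1.0 if (c == "PH" and label) else 0.0) * shift))
           for c in _MED_CATEGORIES}

    rows = []
    for feat in _TEMPORAL:
        n_obs = int(rng.integers(0, 5)) if feat not in _INFORMATIVE else int(rng.integers(1, 6))
        level = _TEMPORAL_BASE[feat] + rng.normal(0, _TEMPORAL_SD[feat])
        level += _INFORMATIVE.get(feat, 0.0) * shift
        level += spec.heterogeneity * _TEMPORAL_SD[feat] * rng.standard_normal()
        for _ in range(n_obs):
            ts = rng.uniform(-6 * 3600.0, window_ends[-1])
            rows.append((ts, feat, level + rng.normal(0, 0.3 * _TEMPORAL_SD[feat])))
    temporal = pd.DataFrame(rows, columns=["timestamp", "feature", "value"])
    temporal = temporal.sort_values("timestamp", kind="stable").reset_index(drop=True)
    return EhrRecord(subject_id=subject_id, static=static, temporal=temporal,
                     med_counts=med)


def generate_cohort(spec: CohortSpec) -> CohortDataset:
    """Draw labels Bernoulli(incidence) and build the per-subject factory."""
    ss = np.random.SeedSequence(spec.seed)
    label_rng = np.random.default_rng(ss.spawn(1)[0])
    labels = (label_rng.random(spec.n_subjects) < spec.incidence).astype(int)
    child_seeds = ss.spawn(spec.n_subjects + 1)[1:]
    ids = [f"{spec.cohort_id}-{i:04d}" for i in range(spec.n_subjects)]
    return CohortDataset(spec=spec, labels=labels, subject_ids=ids,
                         _child_seeds=child_seeds)


def default_cohort_specs(seed: int = 0, gap_hours: float = 0.5,
                         effect_size: float = 1.0) -> dict[str, CohortSpec]:
    """Three cohorts patterned on a cardiac-surgery training cohort and two
    increasingly heterogeneous test cohorts (sizes 423 / 66 / 21, event
    incidences 0.174 / 0.212 / 0.905 at the 0.5 h gap)."""
    return {
        "cohort1": CohortSpec(n_subjects=423, incidence=0.174, effect_size=effect_size,
                              gap_hours=gap_hours, seed=seed, heterogeneity=0.0,
                              cohort_id="c1"),
        "cohort2": CohortSpec(n_subjects=66, incidence=0.212, effect_size=effect_size,
                              gap_hours=gap_hours, seed=seed + 1, heterogeneity=0.5,
                              cohort_id="c2"),
        "cohort3": CohortSpec(n_subjects=21, incidence=0.905, effect_size=effect_size,
                              gap_hours=gap_hours, seed=seed + 2, heterogeneity=1.0,
                              cohort_id="c3"),
    }
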