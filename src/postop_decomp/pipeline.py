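"""End-to-end orchestration: cohorts -> features -> reduction -> models.

The training side fits every reserved artifact on the training cohort only:
entry-wise standardization statistics, the HOSVD feature-mode
transformations, the CP epsilon/window factors A and C, EHR imputation
medians and EHR standardization statistics, and the classifiers.  The test
side reuses them unchanged; a fitted :class:`TrainedPipeline` can be
round-tripped through a bundle directory with a content-hash manifest.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import yaml

from .ehr import EhrSchema, encode_ehr
from .errors import DataError, SubjectExcluded
from .features import (EpsilonGrid, FeatureSet, extract_all_features)
from .models import (MODEL_NAMES, balance_training_set, grid_search_cv,
                     model_scores, repeated_evaluation, train_model)
from .preprocessing import bandpass_filter, segment_tumbling_windows
from .records import WaveformRecord
from .synthetic import CohortDataset, default_ehr_schema
from .tensor_reduction import (DEFAULT_CORE_DIMS, cp_als,
                               hosvd_reduce, project_subject, stack_cohort,
                               stack_feature_mode, standardize,
                               subject_feature_vector, tensor_feature_names)

CHANNELS = ("ECG", "ABP", "PPG")


@dataclass
class CohortFeatures:
    """Extracted features of one cohort (complete subjects only)."""

    cohort_id: str
    subject_ids: list[str]
    featuresets: list[FeatureSet]
    ehr: np.ndarray
    ehr_names: list[str]
    labels: np.ndarray
    excluded: list[str] = field(default_factory=list)


def extract_subject_features(waveforms: dict[str, WaveformRecord],
                             window_minutes: float = 3.0, n_windows: int = 5,
                             grid: EpsilonGrid | None = None,
                             subject_id: str = "") -> FeatureSet:
    """Filter, window and featurize one subject's three channels."""
    missing = [c for c in CHANNELS if c not in waveforms]
    if missing:
        raise SubjectExcluded(f"subject {subject_id!r} missing channels {missing}")
    wins = {c: segment_tumbling_windows(bandpass_filter(waveforms[c]),
                                        window_minutes, n_windows)
            for c in CHANNELS}
    return extract_all_features(wins["ECG"], wins["ABP"], wins["PPG"],
                                grid=grid, subject_id=subject_id)


def extract_cohort_features(cohort: CohortDataset,
                            schema: EhrSchema | None = None,
                            grid: EpsilonGrid | None = None) -> CohortFeatures:
    """Stream a synthetic cohort through preprocessing and feature extraction.

    Subjects with incomplete signals are excluded (and reported), matching
    the cohort-construction rule of the evaluation protocol.
    """
    schema = schema or default_ehr_schema()
    ids, fsets, ehr_rows, labels, excluded = [], [], [], [], []
    ehr_names: list[str] = []
    for i, subj in enumerate(cohort.subjects()):
        try:
            fs = extract_subject_features(
                subj.waveforms, cohort.spec.window_minutes, cohort.spec.n_windows,
                grid=grid, subject_id=subj.subject_id)
        except SubjectExcluded as exc:
            excluded.append(str(exc))
            continue
        vec, names = encode_ehr(subj.ehr, subj.window_end_times, schema)
        if not ehr_names:
            ehr_names = names
        ids.append(subj.subject_id)
        fsets.append(fs)
        ehr_rows.append(vec)
        labels.append(subj.label)
    if not ids:
        raise DataError("no complete subjects in cohort")
    return CohortFeatures(cohort_id=cohort.spec.cohort_id, subject_ids=ids,
                          featuresets=fsets, ehr=np.vstack(ehr_rows),
                          ehr_names=ehr_names, labels=np.asarray(labels),
                          excluded=excluded)


# ---------------------------------------------------------------------------
# reduction fitting / transforming


@dataclass
class TrainedPipeline:
    """All reserved artifacts of a fitted pipeline (a model bundle)."""

    stats_means: dict
    stats_sds: dict
    U: dict
    A: np.ndarray
    C: np.ndarray
    core_dims: dict
    ehr_medians: np.ndarray
    ehr_means: np.ndarray
    ehr_sds: np.ndarray
    ehr_names: list[str]
    feature_names: list[str]
    classifiers: dict = field(default_factory=dict)  # name -> (params, clf)
    config: dict = field(default_factory=dict)

    # -- feature construction ------------------------------------------------

    def tensor_features(self, features: CohortFeatures) -> np.ndarray:
        from .tensor_reduction import StandardizationStats

        stats = StandardizationStats(means=self.stats_means, sds=self.stats_sds)
        tensors = stack_cohort(features.featuresets)
        std, _ = standardize(tensors, stats)
        reduced = {}
        for t, arr in std.items():
            if t in self.U:
                reduced[t], _ = hosvd_reduce(arr, self.U[t].shape[1], U=self.U[t])
            else:
                reduced[t] = arr
        stacked = stack_feature_mode(reduced)
        rows = []
        for j in range(stacked.shape[-1]):
            rf = project_subject(stacked[..., j], self.A, self.C,
                                 subject_id=features.subject_ids[j])
            rows.append(subject_feature_vector(rf))
        return np.vstack(rows)

    def ehr_features(self, features: CohortFeatures) -> np.ndarray:
        X = features.ehr.copy()
        nan = np.isnan(X)
        if nan.any():
            X[nan] = np.broadcast_to(self.ehr_medians, X.shape)[nan]
        return (X - self.ehr_means) / self.ehr_sds

    def design_matrix(self, features: CohortFeatures) -> np.ndarray:
        return np.hstack([self.tensor_features(features), self.ehr_features(features)])


def fit_reduction(train: CohortFeatures, core_dims: dict | None = None,
                  rank: int = 4, seed: int = 0,
                  cp_max_iter: int = 500) -> TrainedPipeline:
    """Fit standardization, HOSVD and CP on the training cohort."""
    core_dims = dict(core_dims or DEFAULT_CORE_DIMS)
    tensors = stack_cohort(train.featuresets)
    std, stats = standardize(tensors, None)
    reduced, U = {}, {}
    for t, arr in std.items():
        if t in core_dims:
            reduced[t], U[t] = hosvd_reduce(arr, core_dims[t])
        else:
            reduced[t] = arr
    T = stack_feature_mode(reduced)
    cp = cp_als(T, r=rank, seed=seed, max_iter=cp_max_iter)

    ehr = train.ehr
    medians = np.nanmedian(ehr, axis=0)
    medians = np.where(np.isnan(medians), 0.0, medians)
    filled = np.where(np.isnan(ehr), medians, ehr)
    means = filled.mean(axis=0)
    sds = filled.std(axis=0)
    sds[sds == 0.0] = 1.0

    p = T.shape[1]
    names = tensor_feature_names(p, rank) + list(train.ehr_names)
    return TrainedPipeline(stats_means=stats.means, stats_sds=stats.sds, U=U,
                           A=cp.A, C=cp.C, core_dims=core_dims,
                           ehr_medians=medians, ehr_means=means, ehr_sds=sds,
                           ehr_names=train.ehr_names, feature_names=names)


def fit_pipeline(train: CohortFeatures, model_names=MODEL_NAMES,
                 seed: int = 0, fast: bool = False,
                 core_dims: dict | None = None, rank: int = 4,
                 pos_frac: float = 0.35, n_folds: int = 3,
                 config: dict | None = None) -> TrainedPipeline:
    """Fit reduction plus balanced, grid-searched classifiers."""
    pipe = fit_reduction(train, core_dims=core_dims, rank=rank, seed=seed)
    X = pipe.design_matrix(train)
    Xb, yb = balance_training_set(X, train.labels, pos_frac=pos_frac, seed=seed)
    for name in model_names:
        params = grid_search_cv(name, Xb, yb, n_folds=n_folds, seed=seed, fast=fast)
        clf = train_model(name, params, Xb, yb, seed=seed)
        pipe.classifiers[name] = (params, clf)
    pipe.config = dict(config or {}, seed=seed, fast=fast, rank=rank,
                       pos_frac=pos_frac, n_folds=n_folds,
                       models=list(model_names))
    return pipe


def evaluate_pipeline(pipe: TrainedPipeline, test: CohortFeatures) -> dict:
    """Score each fitted classifier on a test cohort (AUROC)."""
    from .models import auroc

    X = pipe.design_matrix(test)
    out = {}
    for name, (params, clf) in pipe.classifiers.items():
        try:
            out[name] = auroc(model_scores(name, clf, X), test.labels)
        except DataError:
            out[name] = float("nan")
    return out


def end_to_end_evaluation(train: CohortFeatures,
                          tests: dict[str, CohortFeatures],
                          model_names=("rf",), reps: int = 25,
                          base_seed: int = 0, fast: bool = True,
                          core_dims: dict | None = None):
    """The repeated-evaluation protocol on extracted cohorts.

    Reduction artifacts are fitted once on the full training cohort (they
    depend only on training data); each repetition re-balances, re-searches
    the grids on reshuffled folds, refits and rescores.
    """
    overlap = set(train.subject_ids) & {s for t in tests.values() for s in t.subject_ids}
    if overlap:
        raise DataError(f"train/test subject overlap: {sorted(overlap)[:5]}")
    pipe = fit_reduction(train, core_dims=core_dims, seed=base_seed)
    X_train = pipe.design_matrix(train)
    test_sets = {cid: (pipe.design_matrix(tf), tf.labels) for cid, tf in tests.items()}
    return repeated_evaluation(X_train, train.labels, test_sets,
                               model_names=model_names, reps=reps,
                               base_seed=base_seed, fast=fast), pipe


def planted_effect_experiment(n_train: int = 400, n_test: int = 100,
                              effect_size: float = 1.0, incidence: float = 0.35,
                              reps: int = 25, base_seed: int = 0,
                              model_names=("rf",), fast: bool = True,
                              **cohort_kw):
    """Generate train/test cohorts with a planted pre-event drift, run the
    repeated-evaluation protocol and return (mean, sd) AUROC per model.

    The null condition (``effect_size=0``) must land at chance; a unit
    effect must be recoverable through the full taut-string -> DTCWPT ->
    tensor -> classifier path.
    """
    from .synthetic import CohortSpec, generate_cohort

    spec_tr = CohortSpec(n_subjects=n_train, incidence=incidence,
                         effect_size=effect_size, seed=base_seed * 1000 + 17,
                         cohort_id="pe-train", **cohort_kw)
    spec_te = CohortSpec(n_subjects=n_test, incidence=incidence,
                         effect_size=effect_size, seed=base_seed * 1000 + 18,
                         cohort_id="pe-test", **cohort_kw)
    ftr = extract_cohort_features(generate_cohort(spec_tr))
    fte = extract_cohort_features(generate_cohort(spec_te))
    report, _ = end_to_end_evaluation(ftr, {"test": fte}, model_names=model_names,
                                      reps=reps, base_seed=base_seed, fast=fast)
    return {name: report.summary()[(name, "test")] for name in model_names}


# ---------------------------------------------------------------------------
# bundle serialization


_ARRAY_KEYS = ("A", "C", "ehr_medians", "ehr_means", "ehr_sds")


def save_bundle(pipe: TrainedPipeline, path) -> dict:
    """Write a bundle directory (arrays, schema, classifiers, manifest)."""
    path = Path(path)
    if path.exists():
        shutil.rmtree(path)
    path.mkdir(parents=True)
    try:
        arrays = {k: getattr(pipe, k) for k in _ARRAY_KEYS}
        for t, u in pipe.U.items():
            arrays[f"U_{t}"] = u
        for t in pipe.stats_means:
            arrays[f"mean_{t}"] = pipe.stats_means[t]
            arrays[f"sd_{t}"] = pipe.stats_sds[t]
        np.savez(path / "arrays.npz", **arrays)
        meta = dict(core_dims=pipe.core_dims, ehr_names=pipe.ehr_names,
                    feature_names=pipe.feature_names, config=pipe.config,
                    classifier_params={k: v[0] for k, v in pipe.classifiers.items()})
        (path / "bundle.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
        joblib.dump({k: v[1] for k, v in pipe.classifiers.items()},
                    path / "classifiers.bin")
        manifest = {}
        for f in sorted(p for p in path.iterdir() if p.name != "manifest.json"):
            manifest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except Exception:
        shutil.rmtree(path, ignore_errors=True)  # no partial bundles
        raise


def load_bundle(path) -> TrainedPipeline:
    path = Path(path)
    for required in ("arrays.npz", "bundle.yaml", "classifiers.bin"):
        if not (path / required).exists():
            raise DataError(f"bundle at {path} is missing artifact {required!r}")
    arrays = dict(np.load(path / "arrays.npz"))
    meta = yaml.safe_load((path / "bundle.yaml").read_text())
    clfs = joblib.load(path / "classifiers.bin")
    U = {k[2:]: v for k, v in arrays.items() if k.startswith("U_")}
    means = {k[5:]: v for k, v in arrays.items() if k.startswith("mean_")}
    sds = {k[3:]: v for k, v in arrays.items() if k.startswith("sd_")}
    missing = [t for t in meta["core_dims"] if t not in U]
    if missing:
        raise DataError(f"bundle at {path} lacks U matrices for {missing}")
    pipe = TrainedPipeline(
        stats_means=means, stats_sds=sds, U=U, A=arrays["A"], C=arrays["C"],
        core_dims=meta["core_dims"], ehr_medians=arrays["ehr_medians"],
        ehr_means=arrays["ehr_means"], ehr_sds=arrays["ehr_sds"],
        ehr_names=meta["ehr_names"], feature_names=meta["feature_names"],
        config=meta.get("config", {}))
    params = meta.get("classifier_params", {})
    pipe.classifiers = {k: (params.get(k, {}), v) for k, v in clfs.items()}
    return pipe
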