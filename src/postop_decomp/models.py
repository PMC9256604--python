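"""Classifiers and the repeated cross-validated evaluation protocol.

Four model families are supported: Gaussian naive Bayes (no tuning),
random forest, linear-kernel SVM (box constraint C and a kernel-scale
gamma dividing the inputs), and LUCCK, a similarity-kernel classifier
whose similarity function is

    Q(x) = prod_i (1 + lambda * x_i**2) ** (-theta),    lambda, theta > 0.

The evaluation protocol mirrors a train-on-one-cohort / test-on-others
design: the training cohort is rebalanced to a 0.35/0.65 positive/negative
ratio by discarding excess negatives, hyperparameters are chosen by
stratified 3-fold cross-validated AUROC grid search on the training cohort,
the winning configuration is refitted on all folds, and test cohorts are
scored; the whole procedure is repeated (101 times by default) with
reshuffled folds to yield mean and SD AUROC per model and cohort.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .errors import ArgumentError, DataError

MODEL_NAMES = ("nb", "rf", "svm", "lucck")


# ---------------------------------------------------------------------------
# balancing


def balance_training_set(X: np.ndarray, y: np.ndarray, pos_frac: float = 0.35,
                         seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Discard excess negatives to reach a ``pos_frac`` positive fraction.

    All positives are kept and negatives are subsampled without replacement
    to ``ceil(n_pos * (1 - pos_frac) / pos_frac)``.  A training set that is
    already at least ``pos_frac`` positive passes through unchanged (the
    rule only discards, never oversamples).
    """
    y = np.asarray(y)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if pos.size == 0:
        raise DataError("no positive cases in the training set")
    if pos.size / y.size >= pos_frac:
        return X, y
    n_keep = math.ceil(pos.size * (1.0 - pos_frac) / pos_frac)
    rng = np.random.default_rng(seed)
    kept_neg = rng.choice(neg, size=min(n_keep, neg.size), replace=False)
    idx = np.sort(np.concatenate([pos, kept_neg]))
    return X[idx], y[idx]


# ---------------------------------------------------------------------------
# AUROC


def auroc(scores: np.ndarray, y: np.ndarray) -> float:
    """Rank-statistic AUROC: P(score+ > score-) + 0.5 P(tie).

    Implemented via the Mann-Whitney U statistic with midranks, which
    handles ties exactly.
    """
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUROC undefined: only one class present")
    ranks = rankdata(scores)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# LUCCK


def lucck_similarity(x: np.ndarray, lam: float, theta: float) -> float:
    """Similarity Q of a feature-difference vector (log-space product)."""
    if lam <= 0 or theta <= 0:
        raise ArgumentError("lambda and theta must be positive")
    x = np.asarray(x, dtype=float)
    return float(np.exp(-theta * np.sum(np.log1p(lam * x * x))))


def _lucck_logsum(X_test: np.ndarray, X_train: np.ndarray, lam: float,
                  block: int = 64) -> np.ndarray:
    """Matrix L[t, i] = sum_f log(1 + lam * (x_t - x_i)_f^2), blocked over tests."""
    out = np.empty((X_test.shape[0], X_train.shape[0]))
    for a in range(0, X_test.shape[0], block):
        d = X_test[a:a + block, None, :] - X_train[None, :, :]
        out[a:a + block] = np.log1p(lam * d * d).sum(axis=2)
    return out


class LucckModel:
    """Similarity-mass classifier with shared scalar lambda and theta.

    score(x) = m+ / (m+ + m-) with class-size-normalized similarity masses
    m± = mean over the class of Q(x - x_i); the score is the fraction of
    (class-balanced) similarity mass carried by the positive class.
    """

    def __init__(self, lam: float, theta: float):
        if lam <= 0 or theta <= 0:
            raise ArgumentError("lambda and theta must be positive")
        self.lam = float(lam)
        self.theta = float(theta)
        self._X = None
        self._y = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LucckModel":
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise DataError("LUCCK requires both classes in the training data")
        self._X = np.asarray(X, dtype=float)
        self._y = y
        return self

    @staticmethod
    def scores_from_logsum(L: np.ndarray, y: np.ndarray, theta: float) -> np.ndarray:
        logq = -theta * L
        # normalize in log space for numerical stability on long feature vectors
        ref = logq.max(axis=1, keepdims=True)
        q = np.exp(logq - ref)
        m_pos = q[:, y == 1].mean(axis=1)
        m_neg = q[:, y == 0].mean(axis=1)
        return m_pos / (m_pos + m_neg)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        L = _lucck_logsum(np.asarray(X, dtype=float), self._X, self.lam)
        return self.scores_from_logsum(L, self._y, self.theta)

    predict_proba_positive = decision_function


# ---------------------------------------------------------------------------
# model specs and grids


@dataclass(frozen=True)
class ModelSpec:
    name: str
    params: dict = field(default_factory=dict)


def default_grid(name: str, fast: bool = False, seed: int | None = None) -> list[dict]:
    """Hyperparameter grid for one model family.

    RF: trees {50,75,100} x min leaf {1,5,10,15,20} x max-splits fraction
    {25,50,75,100}% x criterion {gini, entropy} x predictors-to-sample
    {10..100 step 10}.  SVM: box constraint C in [1e-7, 1e12] and kernel
    scale gamma in [1e-12, 1e12], log-spaced.  LUCCK: lambda 0.01..0.10
    step 0.01 x theta 0.1..1.0 step 0.1 (100 pairs).  ``fast`` subsamples
    the RF grid to 12 points (seeded) and coarsens the SVM/LUCCK grids.
    """
    if name == "nb":
        return [{}]
    if name == "rf":
        full = [dict(n_estimators=t, min_samples_leaf=l, max_split_frac=msf,
                     criterion=c, max_features=p)
                for t in (50, 75, 100)
                for l in (1, 5, 10, 15, 20)
                for msf in (0.25, 0.50, 0.75, 1.00)
                for c in ("gini", "entropy")
                for p in range(10, 101, 10)]
        if fast:
            rng = np.random.default_rng(seed)
            idx = rng.choice(len(full), size=12, replace=False)
            return [full[i] for i in sorted(idx)]
        return full
    if name == "svm":
        n = 5 if fast else 20
        return [dict(C=c, gamma=g)
                for c in np.logspace(-7, 12, n)
                for g in np.logspace(-12, 12, n)]
    if name == "lucck":
        lams = np.round(np.arange(1, 11) * 0.01, 2)
        thetas = np.round(np.arange(1, 11) * 0.1, 1)
        if fast:
            lams, thetas = lams[::2], thetas[::2]
        return [dict(lam=float(l), theta=float(t)) for l in lams for t in thetas]
    raise ArgumentError(f"unknown model {name!r}")


def train_model(name: str, params: dict, X: np.ndarray, y: np.ndarray,
                seed: int | None = None):
    """Fit one classifier; every model exposes continuous scores for AUROC."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DataError("degenerate single-class training set")
    if name == "nb":
        return GaussianNB().fit(X, y)
    if name == "rf":
        p = dict(params)
        msf = p.pop("max_split_frac", 1.0)
        max_leaf = max(2, int(round(msf * (len(y) - 1))) + 1)
        mf = p.pop("max_features", None)
        if mf is not None:
            mf = min(int(mf), X.shape[1])
        return RandomForestClassifier(random_state=seed, max_leaf_nodes=max_leaf,
                                      max_features=mf, **p).fit(X, y)
    if name == "svm":
        p = dict(params)
        gamma = p.pop("gamma", 1.0)
        clf = SVC(kernel="linear", C=p.get("C", 1.0), max_iter=200_000)
        clf._kernel_scale = gamma
        return clf.fit(X / gamma, y)
    if name == "lucck":
        return LucckModel(params["lam"], params["theta"]).fit(X, y)
    raise ArgumentError(f"unknown model {name!r}")


def model_scores(name: str, clf, X: np.ndarray) -> np.ndarray:
    """Continuous positive-class scores (margins or probabilities)."""
    if name == "nb":
        return clf.predict_proba(X)[:, 1]
    if name == "rf":
        return clf.predict_proba(X)[:, 1]
    if name == "svm":
        return clf.decision_function(X / clf._kernel_scale)
    return clf.decision_function(X)


# ---------------------------------------------------------------------------
# grid search


def grid_search_cv(name: str, X: np.ndarray, y: np.ndarray, n_folds: int = 3,
                   seed: int | None = None, grid: list[dict] | None = None,
                   fast: bool = False) -> dict:
    """Pick the grid point maximizing mean validation AUROC.

    Stratified folds; ties broken by first-in-grid order.  LUCCK is
    evaluated with a lambda-factorized fast path (the theta dimension
    reuses the pairwise log-sums).
    """
    if n_folds < 2:
        raise ArgumentError("need at least 2 folds")
    y = np.asarray(y)
    if grid is None:
        grid = default_grid(name, fast=fast, seed=seed)
    if len(grid) == 1:
        return grid[0]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    for _, va in folds:
        if len(np.unique(y[va])) < 2:
            raise DataError("a validation fold contains one class")

    if name == "lucck":
        lams = sorted({g["lam"] for g in grid})
        thetas = sorted({g["theta"] for g in grid})
        mean_auc = {}
        for lam in lams:
            per_theta = np.zeros(len(thetas))
            for tr, va in folds:
                L = _lucck_logsum(X[va], X[tr], lam)
                for ti, theta in enumerate(thetas):
                    s = LucckModel.scores_from_logsum(L, y[tr], theta)
                    per_theta[ti] += auroc(s, y[va])
            for ti, theta in enumerate(thetas):
                mean_auc[(lam, theta)] = per_theta[ti] / len(folds)
        best = max(grid, key=lambda g: (mean_auc[(g["lam"], g["theta"])],
                                        -grid.index(g)))
        return best

    best_params, best_auc = grid[0], -np.inf
    for params in grid:
        aucs = []
        for tr, va in folds:
            clf = train_model(name, params, X[tr], y[tr], seed=seed)
            aucs.append(auroc(model_scores(name, clf, X[va]), y[va]))
        m = float(np.mean(aucs))
        if m > best_auc:
            best_auc, best_params = m, params
    return best_params


# ---------------------------------------------------------------------------
# repeated evaluation


@dataclass
class EvaluationReport:
    """Per model x test-cohort mean/SD AUROC over repetitions."""

    per_rep: dict  # (model, cohort) -> list of AUROCs (NaN when undefined)
    reps: int
    base_seed: int

    def summary(self) -> dict:
        out = {}
        for (model, cohort), vals in self.per_rep.items():
            arr = np.asarray(vals, dtype=float)
            ok = arr[np.isfinite(arr)]
            out[(model, cohort)] = (float(np.mean(ok)) if ok.size else float("nan"),
                                    float(np.std(ok)) if ok.size else float("nan"))
        return out

    def to_frame(self):
        import pandas as pd

        rows = []
        for (model, cohort), (m, s) in self.summary().items():
            rows.append(dict(model=model, cohort=cohort, mean_auroc=m, sd_auroc=s,
                             reps=self.reps))
        return pd.DataFrame(rows)


def repeated_evaluation(X_train: np.ndarray, y_train: np.ndarray,
                        test_sets: dict[str, tuple[np.ndarray, np.ndarray]],
                        model_names=("nb", "rf", "svm", "lucck"),
                        reps: int = 101, base_seed: int = 0, n_folds: int = 3,
                        fast: bool = False, pos_frac: float = 0.35,
                        include_train_eval: bool = False) -> EvaluationReport:
    """Repeat balance -> grid-search -> refit -> score ``reps`` times.

    Each repetition draws its own fold shuffle and negative subsample from
    ``base_seed + rep``; the report is bit-reproducible from ``base_seed``.
    Test cohorts with a single class get NaN entries and a warning.
    """
    per_rep: dict = {}
    for rep in range(reps):
        seed = base_seed + rep
        Xb, yb = balance_training_set(X_train, y_train, pos_frac=pos_frac, seed=seed)
        for name in model_names:
            params = grid_search_cv(name, Xb, yb, n_folds=n_folds, seed=seed, fast=fast)
            clf = train_model(name, params, Xb, yb, seed=seed)
            targets = dict(test_sets)
            if include_train_eval:
                targets = {"train": (X_train, y_train), **targets}
            for cohort, (Xt, yt) in targets.items():
                try:
                    a = auroc(model_scores(name, clf, Xt), yt)
                except DataError:
                    warnings.warn(f"cohort {cohort!r} has one class; AUROC undefined")
                    a = float("nan")
                per_rep.setdefault((name, cohort), []).append(a)
    return EvaluationReport(per_rep=per_rep, reps=reps, base_seed=base_seed)
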