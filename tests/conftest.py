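"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize

from postop_decomp import (CohortSpec, design_qshift_filterbank,
                           extract_cohort_features, generate_cohort)


@pytest.fixture(scope="session")
def filterbank():
    return design_qshift_filterbank(2)


#: reduced-scale study conditions for cheap end-to-end tests: shorter
#: tumbling windows and lower sampling rates keep the per-subject cost low
#: while exercising every stage
SMALL_COHORT_KW = dict(window_minutes=1.0, fs_ecg=120.0, fs_abp=60.0, fs_ppg=60.0)


def make_small_features(n, incidence, effect, seed, cohort_id):
    spec = CohortSpec(n_subjects=n, incidence=incidence, effect_size=effect,
                      seed=seed, cohort_id=cohort_id, **SMALL_COHORT_KW)
    return extract_cohort_features(generate_cohort(spec))


@pytest.fixture(scope="session")
def small_train_features():
    return make_small_features(36, 0.4, 1.2, 11, "sm-train")


@pytest.fixture(scope="session")
def small_test_features():
    return make_small_features(18, 0.4, 1.2, 12, "sm-test")


# ---------------------------------------------------------------------------
# oracles


def taut_string_qp_oracle(f: np.ndarray, eps: float) -> float:
    """Minimal ||diff(g)||_2 over the box f +/- eps, by constrained
    optimization with an exact active-set polish.  Independent of the
    corridor-walk implementation."""
    n = len(f)
    lo, hi = f - eps, f + eps

    def obj(g):
        d = np.diff(g)
        return d @ d

    def jac(g):
        d = np.diff(g)
        gr = np.zeros_like(g)
        gr[:-1] -= 2 * d
        gr[1:] += 2 * d
        return gr

    res = minimize(obj, (lo + hi) / 2, jac=jac, method="L-BFGS-B",
                   bounds=list(zip(lo, hi)),
                   options=dict(ftol=1e-18, gtol=1e-14, maxiter=20000))
    g = res.x
    for _ in range(8):
        act_lo = g - lo < 1e-9
        act_hi = hi - g < 1e-9
        g_prev = g.copy()
        free = ~(act_lo | act_hi)
        if free.any() and not free.all():
            # pinned actives + discrete Laplace equations on the free set
            A = np.zeros((n, n))
            b = np.zeros(n)
            for i in range(n):
                if not free[i]:
                    A[i, i] = 1.0
                    b[i] = lo[i] if act_lo[i] else hi[i]
                elif i == 0:
                    A[i, 0], A[i, 1] = 1.0, -1.0
                elif i == n - 1:
                    A[i, n - 1], A[i, n - 2] = 1.0, -1.0
                else:
                    A[i, i - 1], A[i, i], A[i, i + 1] = -1.0, 2.0, -1.0
            try:
                g_new = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                break
            if np.all(g_new >= lo - 1e-12) and np.all(g_new <= hi + 1e-12):
                g = np.clip(g_new, lo, hi)
        if np.allclose(g, g_prev, atol=1e-14):
            break
    return float(np.sqrt(obj(g)))


def auroc_pair_oracle(scores: np.ndarray, y: np.ndarray) -> float:
    """Brute-force O(n^2) pairwise counting AUROC."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
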