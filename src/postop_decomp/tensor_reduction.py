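"""Tensor formation and reduction of the signal feature space.

Per feature type, the (epsilon x feature x window) arrays of the training
subjects are standardized entry-wise (training mean/SD, reused verbatim at
test time), stacked along a fourth subject mode, and the wide types
(DTCWPT, ABP, PPG) are compressed along the feature mode by truncated
higher-order SVD.  All types are then stacked along the feature mode into
one fourth-order tensor ``T`` of shape (5 x 96 x 5 x N_train) under the
default core sizes (DTCWPT 60, ABP 12, PPG 12; ECG/HRV kept whole), and a
rank-4 canonical polyadic (CP) decomposition ``T ~ sum_i a_i o b_i o c_i o
d_i`` is fitted by alternating least squares.  The epsilon-mode factor ``A``
and window-mode factor ``C`` are reserved; any subject's standardized,
HOSVD-reduced (5 x 96 x 5) array ``S`` is then projected to its feature
matrix by the least-squares solution

    B = S_(2) (C (.) A) (A'A * C'C)^+

where ``(.)`` is the Khatri-Rao product, ``*`` the Hadamard product and
``^+`` the Moore-Penrose pseudoinverse.  Flattening ``B`` (feature-major)
gives the 96 x 4 = 384-dimensional tensor feature vector.  Training-subject
feature vectors are computed with the same projection so train and test
features live in the same space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ArgumentError, DataError
from .features import FEATURE_TYPES, FeatureSet

#: default core feature dimensions (identity for ECG/HRV)
DEFAULT_CORE_DIMS = {"DTCWPT": 60, "ABP": 12, "PPG": 12}

REDUCED_TYPES = ("DTCWPT", "ABP", "PPG")


@dataclass
class StandardizationStats:
    """Per (type, epsilon, window, feature) training mean and SD.

    Zero-variance entries get SD 1 so standardized values are exactly 0.
    """

    means: dict[str, np.ndarray]
    sds: dict[str, np.ndarray]


def stack_cohort(featuresets: list[FeatureSet]) -> dict[str, np.ndarray]:
    """Stack per-subject arrays into (eps, feature, window, subject) tensors."""
    if not featuresets:
        raise DataError("empty cohort")
    return {t: np.stack([fs.arrays[t] for fs in featuresets], axis=-1)
            for t in FEATURE_TYPES}


def standardize(tensors: dict[str, np.ndarray],
                stats: StandardizationStats | None = None
                ) -> tuple[dict[str, np.ndarray], StandardizationStats]:
    """Entry-wise standardization across the subject mode.

    In training mode (``stats is None``) the statistics are fitted; in test
    mode the supplied training statistics are applied unchanged.
    """
    if not tensors or any(v.shape[-1] == 0 for v in tensors.values()):
        raise DataError("empty cohort")
    if stats is None:
        means = {t: v.mean(axis=-1) for t, v in tensors.items()}
        sds = {}
        for t, v in tensors.items():
            sd = v.std(axis=-1)
            sd[sd == 0.0] = 1.0  # zero-variance guard
            sds[t] = sd
        stats = StandardizationStats(means=means, sds=sds)
    out = {t: (v - stats.means[t][..., None]) / stats.sds[t][..., None]
           for t, v in tensors.items()}
    return out, stats


def hosvd_reduce(tensor: np.ndarray, core_feature_dim: int,
                 U: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Truncated HOSVD along the feature mode (mode 2) of a 4-mode tensor.

    Returns ``(cores, U)`` where ``U`` (features x core_feature_dim) holds
    the leading left singular vectors of the mode-2 unfolding and ``cores``
    is the tensor multiplied by ``U^T`` along mode 2.  Pass a reserved ``U``
    to reduce test subjects with the training transformation.
    """
    n_feat = tensor.shape[1]
    if core_feature_dim > n_feat:
        raise ArgumentError(f"core dim {core_feature_dim} exceeds feature dim {n_feat}")
    if U is None:
        unfolding = np.moveaxis(tensor, 1, 0).reshape(n_feat, -1, order="F")
        U_full, _, _ = np.linalg.svd(unfolding, full_matrices=False)
        U = U_full[:, :core_feature_dim]
    cores = np.tensordot(U.T, tensor, axes=([1], [1])).transpose(1, 0, 2, 3)
    return cores, U


def mode2_truncation_energy(tensor: np.ndarray, core_feature_dim: int) -> float:
    """Energy of the discarded mode-2 singular values (reconstruction bound)."""
    unfolding = np.moveaxis(tensor, 1, 0).reshape(tensor.shape[1], -1, order="F")
    s = np.linalg.svd(unfolding, compute_uv=False)
    return float(np.sum(s[core_feature_dim:] ** 2))


def stack_feature_mode(tensors: dict[str, np.ndarray],
                       order: tuple = FEATURE_TYPES) -> np.ndarray:
    """Stack per-type (5 x f_t x 5 x N) tensors along the feature mode."""
    shapes = {t: tensors[t].shape for t in order}
    ref = next(iter(shapes.values()))
    for t, s in shapes.items():
        if (s[0], s[2], s[3]) != (ref[0], ref[2], ref[3]):
            raise DataError(f"type {t} has mismatched epsilon/window/subject dims {s}")
    return np.concatenate([tensors[t] for t in order], axis=1)


# ---------------------------------------------------------------------------
# CP-ALS


def khatri_rao(mats: list[np.ndarray]) -> np.ndarray:
    """Column-wise Kronecker product (first matrix's rows vary slowest)."""
    r = mats[0].shape[1]
    out = mats[0]
    for m in mats[1:]:
        out = (out[:, None, :] * m[None, :, :]).reshape(-1, r)
    return out


def _unfold(T: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(T, mode, 0).reshape(T.shape[mode], -1, order="F")


@dataclass
class CpModel:
    """Rank-r CP factors of the stacked training tensor (modes eps, feature,
    window, subject) and the achieved fit ``||T - T_hat||``."""

    factors: list[np.ndarray]
    rank: int
    fit_history: list[float] = field(default_factory=list)

    @property
    def A(self) -> np.ndarray:  # epsilon mode, 5 x r
        return self.factors[0]

    @property
    def B(self) -> np.ndarray:  # feature mode
        return self.factors[1]

    @property
    def C(self) -> np.ndarray:  # window mode, 5 x r
        return self.factors[2]

    @property
    def D(self) -> np.ndarray:  # subject mode
        return self.factors[3]

    def reconstruct(self) -> np.ndarray:
        A, B, C, D = self.factors
        T = np.einsum("ir,jr,kr,lr->ijkl", A, B, C, D)
        return T


def cp_als(T: np.ndarray, r: int = 4, max_iter: int = 500, tol: float = 1e-8,
           seed: int | None = 0) -> CpModel:
    """Canonical polyadic decomposition by alternating least squares.

    Random-normal initialization (seed-controlled); stops when the relative
    change of the fit drops below ``tol`` or after ``max_iter`` sweeps.  The
    Frobenius objective is non-increasing over sweeps.
    """
    if r < 1:
        raise ArgumentError("rank must be >= 1")
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise DataError("tensor contains non-finite entries")
    rng = np.random.default_rng(seed)
    factors = [rng.normal(size=(dim, r)) for dim in T.shape]
    norm_T = np.linalg.norm(T)
    unfoldings = [_unfold(T, m) for m in range(T.ndim)]
    fit_prev = np.inf
    history: list[float] = []
    for _ in range(max_iter):
        for mode in range(T.ndim):
            others = [factors[m] for m in reversed(range(T.ndim)) if m != mode]
            kr = khatri_rao(others)
            gram = np.ones((r, r))
            for m in range(T.ndim):
                if m != mode:
                    gram *= factors[m].T @ factors[m]
            factors[mode] = unfoldings[mode] @ kr @ np.linalg.pinv(gram)
        resid = unfoldings[-1] - factors[-1] @ khatri_rao(
            [factors[m] for m in reversed(range(T.ndim - 1))]).T
        fit = float(np.linalg.norm(resid))
        history.append(fit)
        if norm_T > 0 and abs(fit_prev - fit) <= tol * norm_T:
            break
        fit_prev = fit
    return CpModel(factors=factors, rank=r, fit_history=history)


# ---------------------------------------------------------------------------
# out-of-sample projection


@dataclass
class ReducedSubjectFeatures:
    subject_id: str
    B: np.ndarray  # (stacked reduced feature dim) x r

    @property
    def vector(self) -> np.ndarray:
        return subject_feature_vector(self)


def project_subject(S: np.ndarray, A: np.ndarray, C: np.ndarray,
                    subject_id: str = "") -> ReducedSubjectFeatures:
    """Least-squares projection of one subject's (5 x p x 5) array.

    Solves ``min_B ||S - B (C (.) A)^T||`` in closed form,
    ``B = S_(2) (C (.) A)(A^T A * C^T C)^+``.
    """
    if S.ndim != 3:
        raise ArgumentError("S must be a 3-mode array (epsilon x feature x window)")
    if S.shape[0] != A.shape[0] or S.shape[2] != C.shape[0]:
        raise ArgumentError(
            f"subject array shape {S.shape} incompatible with A {A.shape} / C {C.shape}")
    S2 = _unfold(S, 1)  # p x (5*5), columns ordered (eps fastest, window slowest)
    kr = khatri_rao([C, A])  # rows ordered to match: eps varies fastest
    gram = (A.T @ A) * (C.T @ C)
    B = S2 @ kr @ np.linalg.pinv(gram)
    return ReducedSubjectFeatures(subject_id=subject_id, B=B)


def projection_residual(S: np.ndarray, B: np.ndarray, A: np.ndarray, C: np.ndarray) -> float:
    """``||S - B (C (.) A)^T||`` for a candidate feature matrix B."""
    S2 = _unfold(S, 1)
    return float(np.linalg.norm(S2 - B @ khatri_rao([C, A]).T))


def subject_feature_vector(rf: ReducedSubjectFeatures) -> np.ndarray:
    """Feature-major flattening of B (row-major over features, then ranks)."""
    return np.ascontiguousarray(rf.B).reshape(-1)


def tensor_feature_names(p: int, r: int) -> list[str]:
    return [f"ReducedTensor.f{i}.r{c}" for i in range(p) for c in range(r)]
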