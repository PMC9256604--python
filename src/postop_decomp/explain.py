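"""Model-agnostic Shapley attribution by permutation sampling.

For a score function f and a sample x, the Shapley value of feature i is
the average, over orderings of the features, of the change in f when
feature i switches from a background value to x_i given that the features
before it in the ordering have already switched.  The estimator draws a
random ordering and a random background row per draw and averages the
marginal contributions, so for every explained sample the attributions sum
to f(x) minus the mean background score (local additivity) up to
Monte-Carlo error.  Mean attributions across the training data summarise
which features push the model towards the positive (deterioration) or
negative class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ArgumentError, DataError


@dataclass
class ShapleyReport:
    feature_names: list[str]
    mean_values: np.ndarray
    base_value: float
    n_samples: int
    per_sample: np.ndarray | None = None
    per_sample_scores: np.ndarray | None = None


def mean_shapley(score_fn, X: np.ndarray, n_permutations: int = 64,
                 seed: int | None = 0, feature_names: list[str] | None = None,
                 background: np.ndarray | None = None,
                 max_background: int = 100,
                 keep_per_sample: bool = False) -> ShapleyReport:
    """Mean permutation-sampling Shapley values over the rows of ``X``.

    ``score_fn`` maps an (n, p) array to n continuous scores.  The
    background set defaults to up to ``max_background`` rows of ``X``
    (seeded subsample).  Fully deterministic for a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise DataError("X must be a non-empty 2-D array")
    if n_permutations < 1:
        raise ArgumentError("n_permutations must be >= 1")
    n, p = X.shape
    rng = np.random.default_rng(seed)
    if background is None:
        background = X
    background = np.asarray(background, dtype=float)
    if background.shape[0] > max_background:
        pick = rng.choice(background.shape[0], size=max_background, replace=False)
        background = background[pick]
    base_value = float(np.mean(score_fn(background)))

    phi = np.zeros((n, p))
    scores = np.asarray(score_fn(X), dtype=float)
    for s in range(n):
        x = X[s]
        contrib = np.zeros(p)
        for draw in range(n_permutations):
            # cycle the background rows: the background average is then
            # exact whenever n_permutations is a multiple of the set size
            b = background[draw % background.shape[0]]
            order = rng.permutation(p)
            # walk the permutation: switch features of b to x one at a time
            stack = np.tile(b, (p + 1, 1))
            mask = np.zeros(p, dtype=bool)
            for step, j in enumerate(order, start=1):
                mask[j] = True
                stack[step, mask] = x[mask]
            vals = np.asarray(score_fn(stack), dtype=float)
            contrib[order] += np.diff(vals)
        phi[s] = contrib / n_permutations
    report = ShapleyReport(
        feature_names=feature_names or [f"f{i}" for i in range(p)],
        mean_values=phi.mean(axis=0),
        base_value=base_value,
        n_samples=n,
        per_sample=phi if keep_per_sample else None,
        per_sample_scores=scores if keep_per_sample else None,
    )
    return report


def top_features(report: ShapleyReport, n: int = 10) -> tuple[list, list]:
    """The ``n`` most positive and ``n`` most negative mean attributions.

    Returns two lists of (name, value), each sorted by value (descending
    for the positive list, ascending for the negative); ties broken
    lexicographically by name.
    """
    pairs = list(zip(report.feature_names, report.mean_values))
    n = min(n, len(pairs))
    pos = sorted(pairs, key=lambda t: (-t[1], t[0]))[:n]
    neg = sorted(pairs, key=lambda t: (t[1], t[0]))[:n]
    return pos, neg


def plot_top_features(report: ShapleyReport, n: int = 10, path=None):
    """Horizontal bar chart of the top positive/negative mean attributions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos, neg = top_features(report, n)
    rows = pos[::-1] + neg[::-1]
    names = [r[0] for r in rows]
    vals = [r[1] for r in rows]
    fig, ax = plt.subplots(figsize=(8, 0.35 * len(rows) + 1.5))
    colors = ["#c0392b" if v >= 0 else "#2980b9" for v in vals]
    ax.barh(range(len(rows)), vals, color=colors)
    ax.set_yticks(range(len(rows)), names, fontsize=7)
    ax.axvline(0.0, color="k", lw=0.8)
    ax.set_xlabel("mean Shapley value")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
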