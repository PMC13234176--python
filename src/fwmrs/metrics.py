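"""Evaluation machinery: weighted MMD, the corrected repeated-CV t-test,
and Benjamini-Hochberg adjustment.

The weighted maximum mean discrepancy between weighted samples X, Y is

    MMD^2 = sum_ij wX_i wX_j k(x_i, x_j) - 2 sum_ij wX_i wY_j k(x_i, y_j)
            + sum_ij wY_i wY_j k(y_i, y_j)

with each weight vector normalized to sum 1 (a discrepancy of weighted
empirical measures) and the feature-weighted RBF kernel

    k(x, y; w_f) = exp(- sum_j w_f_j (x_j - y_j)^2 / (2 sigma^2)).

The bandwidth heuristic sets sigma to the mean pairwise Euclidean distance
over the pooled rows of both samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import t as t_dist
from sklearn.metrics.pairwise import euclidean_distances
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairedScoreSeries",
    "heuristic_sigma",
    "weighted_mmd",
    "corrected_cv_ttest",
    "benjamini_hochberg",
]


def heuristic_sigma(X, max_rows: int = 2000, seed: int = 0) -> float:
    """Mean Euclidean distance over all unordered row pairs of ``X``.

    Exact up to ``max_rows`` rows; above that a seeded subsample of
    ``max_rows`` rows is used.  Returns 0.0 for degenerate (all-identical)
    input, which callers must treat as an error for kernel use.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    if len(X) > max_rows:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(len(X), size=max_rows, replace=False)]
    return float(pdist(X).mean())


def _normalized(w, n, name):
    if w is None:
        return np.full(n, 1.0 / n)
    w = np.asarray(w, dtype=np.float64)
    if w.shape != (n,):
        raise ValueError(f"{name} has length {w.shape}, expected {n}")
    total = w.sum()
    if total <= 0:
        raise ValueError(f"{name} sums to {total}; must be positive")
    return w / total


def weighted_mmd(X, Y, w_X=None, w_Y=None, w_f=None, sigma: float = 1.0) -> float:
    """Weighted MMD between samples X and Y under the feature-weighted RBF kernel.

    Sample weights default to uniform and are normalized to sum 1; feature
    weights default to uniform 1/p.  A negative radicand within -1e-12
    (floating-point cancellation when the measures coincide) is clamped to 0.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must share columns")
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    p = X.shape[1]
    wf = np.full(p, 1.0 / p) if w_f is None else np.asarray(w_f, dtype=np.float64)
    if wf.shape != (p,):
        raise ValueError("feature weights must have one entry per column")
    wx = _normalized(w_X, len(X), "w_X")
    wy = _normalized(w_Y, len(Y), "w_Y")
    scale = np.sqrt(wf)
    Xs, Ys = X * scale, Y * scale
    gamma = 1.0 / (2.0 * sigma**2)

    def k(A, B):
        return np.exp(-gamma * euclidean_distances(A, B, squared=True))

    mmd2 = wx @ k(Xs, Xs) @ wx - 2.0 * wx @ k(Xs, Ys) @ wy + wy @ k(Ys, Ys) @ wy
    if mmd2 < -1e-12:
        raise FloatingPointError(f"MMD^2 = {mmd2} is negative beyond tolerance")
    return float(np.sqrt(max(mmd2, 0.0)))


@dataclass
class PairedScoreSeries:
    """Aligned per-fold metric values of two methods over r repeats x k folds."""

    scores_a: np.ndarray
    scores_b: np.ndarray
    n_train: int
    n_test: int

    def __post_init__(self) -> None:
        a = np.asarray(self.scores_a, dtype=float)
        b = np.asarray(self.scores_b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("score series must be aligned vectors")
        if len(a) < 2:
            raise ValueError("need at least two paired folds")
        if self.n_train <= 0 or self.n_test <= 0:
            raise ValueError("n_train and n_test must be positive")
        self.scores_a, self.scores_b = a, b

    @property
    def differences(self) -> np.ndarray:
        return self.scores_a - self.scores_b


def corrected_cv_ttest(series: PairedScoreSeries) -> tuple[float, float]:
    """Corrected repeated k-fold cross-validation t-test.

    With per-fold differences d_j (j = 1..n, n = r*k), the statistic is

        t = mean(d) / sqrt((1/n + n_test/n_train) * var(d)),

    where the n_test/n_train term inflates the variance to account for the
    correlation induced by overlapping training sets; the two-sided p-value
    uses n - 1 degrees of freedom.

    Zero variance is signaled explicitly: t = 0, p = 1 when the mean is also
    zero, otherwise p = 0 with an infinite t.
    """
    d = series.differences
    n = len(d)
    m = float(d.mean())
    s2 = float(d.var(ddof=1))
    # degenerate: variance exactly zero, or zero up to rounding of the mean
    if s2 <= np.finfo(float).eps ** 2 * max(m * m, np.finfo(float).tiny):
        if m == 0.0:
            return 0.0, 1.0
        return float(np.sign(m)) * np.inf, 0.0
    correction = 1.0 / n + series.n_test / series.n_train
    t = m / np.sqrt(correction * s2)
    p = 2.0 * float(t_dist.sf(abs(t), df=n - 1))
    return float(t), min(p, 1.0)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up false-discovery-rate adjustment, returned in original order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
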