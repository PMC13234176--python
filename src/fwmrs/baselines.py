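"""Comparator sample-weighting methods: uniform, plain MRS, KMM, and PSA.

Kernel mean matching (KMM) reweights the non-representative rows so their
kernel mean matches the representative one, by solving the quadratic program

    min_w  1/2 w' K_NN w - kappa' w
    s.t.   0 <= w_i <= B,   |sum_i w_i - n_N| <= n_N * eps,

with K the RBF Gram matrix of N and kappa_i = (n_N/n_R) sum_j k(x_i, x_j^R).
Propensity score adjustment (PSA) fits an l2-regularized logistic regression
for the probability pi of a row belonging to the non-representative sample
and weights each row by (1 - pi) / pi.  Both expect standardized encodings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, minimize
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression
from sklearn.metrics.pairwise import rbf_kernel

from .core import FWMRS, DebiasResult, FWMRSConfig, run_fwmrs
from .data_model import Dataset, FeatureWeights, SampleWeights
from .metrics import heuristic_sigma

__all__ = [
    "KMMConfig",
    "UniformWeighting",
    "MRS",
    "KernelMeanMatching",
    "PropensityScoreAdjustment",
    "uniform_weights",
    "run_mrs",
    "kmm_weights",
    "psa_weights",
]

_CLIP = 1e-6


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, Dataset):
        return X.values
    values = getattr(X, "values", X)
    if callable(getattr(values, "to_numpy", None)):
        values = values.to_numpy()
    return np.asarray(values, dtype=np.float64)


@dataclass
class KMMConfig:
    """KMM quadratic-program constants.

    sigma : positive bandwidth, or "heuristic" for the mean pairwise
        Euclidean distance over the pooled N and R rows.
    B : upper bound on individual weights (default 1000).
    eps : slack of the sum constraint; None means (sqrt(n) - 1)/sqrt(n).
    """

    sigma: float | str = "heuristic"
    B: float = 1000.0
    eps: float | None = None

    def __post_init__(self) -> None:
        if self.B <= 0:
            raise ValueError("B must be positive")
        if self.eps is not None and self.eps < 0:
            raise ValueError("eps must be nonnegative")


class UniformWeighting(BaseEstimator):
    """The do-nothing baseline: every sample keeps weight 1."""

    def fit(self, N, R=None):
        Xn = _as_matrix(N)
        if len(Xn) == 0:
            raise ValueError("N is empty")
        self.sample_weights_ = np.ones(len(Xn))
        self.feature_weights_ = FeatureWeights.uniform(Xn.shape[1])
        self.status_ = "converged"
        return self


class MRS(FWMRS):
    """Plain maximum representative subsampling: the loop with exactly
    uniform feature weights (no importance estimation)."""

    _uniform_feature_weights = True

    def __init__(self, n_trees=200, min_weight_fraction_leaf=0.0, C=1.0,
                 classifier="random_forest", n_folds=5, drop_per_iteration=1,
                 auroc_stop_threshold=0.5, max_iterations=None, random_state=None):
        super().__init__(
            temperature=1.0,  # unused: feature weights are fixed uniform
            classifier=classifier, n_trees=n_trees,
            min_weight_fraction_leaf=min_weight_fraction_leaf, C=C,
            n_folds=n_folds, drop_per_iteration=drop_per_iteration,
            auroc_stop_threshold=auroc_stop_threshold,
            max_iterations=max_iterations, random_state=random_state)


class KernelMeanMatching(BaseEstimator):
    """KMM sample reweighting via the RBF kernel-mean quadratic program."""

    def __init__(self, sigma="heuristic", B=1000.0, eps=None):
        self.sigma = sigma
        self.B = B
        self.eps = eps

    def fit(self, N, R):
        Xn, Xr = _as_matrix(N), _as_matrix(R)
        if len(Xn) == 0 or len(Xr) == 0:
            raise ValueError("both N and R must be non-empty")
        cfg = KMMConfig(self.sigma, self.B, self.eps)
        if cfg.sigma == "heuristic":
            sigma = heuristic_sigma(np.vstack([Xn, Xr]))
        else:
            sigma = float(cfg.sigma)
        if sigma <= 0:
            raise ValueError("degenerate bandwidth: pooled rows are identical")
        n, m = len(Xn), len(Xr)
        eps = cfg.eps if cfg.eps is not None else (np.sqrt(n) - 1) / np.sqrt(n)
        gamma = 1.0 / (2.0 * sigma**2)
        K = rbf_kernel(Xn, Xn, gamma=gamma)
        K = K + 1e-8 * np.eye(n)  # ridge for strict positive definiteness
        kappa = (n / m) * rbf_kernel(Xn, Xr, gamma=gamma).sum(axis=1)
        res = minimize(
            lambda w: 0.5 * w @ K @ w - kappa @ w,
            x0=np.ones(n),
            jac=lambda w: K @ w - kappa,
            hess=lambda w: K,
            method="trust-constr",
            bounds=Bounds(0.0, cfg.B),
            constraints=[LinearConstraint(np.ones((1, n)), n * (1 - eps), n * (1 + eps))],
            options={"gtol": 1e-10, "xtol": 1e-12, "maxiter": 500},
        )
        if not res.success and res.status not in (1, 2):
            raise RuntimeError(f"KMM quadratic program failed: {res.message}")
        self.sigma_ = sigma
        self.sample_weights_ = np.clip(res.x, 0.0, cfg.B)
        self.status_ = "converged"
        return self


class PropensityScoreAdjustment(BaseEstimator):
    """Inverse-propensity weighting (1 - pi)/pi from a participation model.

    pi is the l2-regularized logistic-regression probability of a row
    belonging to the non-representative sample (label 1; R is label 0),
    clipped to (1e-6, 1 - 1e-6) so weights stay finite.
    """

    def __init__(self, C=1.0, random_state=None):
        self.C = C
        self.random_state = random_state

    def fit(self, N, R):
        Xn, Xr = _as_matrix(N), _as_matrix(R)
        if len(Xn) == 0 or len(Xr) == 0:
            raise ValueError("both N and R must be non-empty")
        X = np.vstack([Xn, Xr])
        y = np.concatenate([np.ones(len(Xn), dtype=int), np.zeros(len(Xr), dtype=int)])
        lr = LogisticRegression(C=self.C, max_iter=1000, random_state=self.random_state)
        lr.fit(X, y)
        pi = np.clip(lr.predict_proba(Xn)[:, 1], _CLIP, 1 - _CLIP)
        self.propensities_ = pi
        self.sample_weights_ = (1 - pi) / pi
        self.status_ = "converged"
        return self


def uniform_weights(N) -> SampleWeights:
    """All-ones sample weights over N."""
    return SampleWeights(UniformWeighting().fit(N).sample_weights_)


def run_mrs(N, R, cfg: FWMRSConfig) -> DebiasResult:
    """Plain subsampling: the loop with the exact uniform feature-weight vector."""
    p = _as_matrix(N).shape[1]
    return run_fwmrs(N, R, cfg, feature_weights_override=FeatureWeights.uniform(p))


def kmm_weights(N, R, cfg: KMMConfig | None = None) -> SampleWeights:
    cfg = cfg or KMMConfig()
    est = KernelMeanMatching(cfg.sigma, cfg.B, cfg.eps).fit(N, R)
    return SampleWeights(est.sample_weights_)


def psa_weights(N, R, C: float = 1.0) -> SampleWeights:
    est = PropensityScoreAdjustment(C=C).fit(N, R)
    return SampleWeights(est.sample_weights_)
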