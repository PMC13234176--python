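"""Domain-classifier feature importances and their softmin transformation.

The degree to which each feature is biased is read off a domain classifier
trained to distinguish the representative sample R (label 1) from the
non-representative sample N (label 0): features the classifier leans on are
exactly those whose distributions differ.  Per-feature importance is the
mean absolute Shapley attribution over the pooled rows (tree-path
attributions with interventional perturbation for the forest family,
closed-form linear Shapley for the SVM family; permutation importance is
selectable for large inputs).  The softmin transformation

    w_i = exp(-I_i / t) / sum_j exp(-I_j / t)

then converts importances into a simplex of feature weights: low temperature
t concentrates weight on the least biased feature, high t approaches
uniform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from ._treeshap import forest_interventional_shap
from .data_model import FeatureWeights
from .weighted_learners import FeatureWeightedLinearSVM, auroc

__all__ = [
    "DomainClassifierSpec",
    "ImportanceVector",
    "train_domain_classifier",
    "estimate_importance",
    "softmin_weights",
]

FAMILIES = ("random_forest", "linear_svm")


@dataclass
class DomainClassifierSpec:
    """Configuration of the domain classifier.

    family : "random_forest" or "linear_svm"
    n_trees : forest size (forest family), default 200
    min_weight_fraction_leaf : leaf regularization of the forest
    C : l2 regularization strength (SVM family)
    random_seed : seed for training and for attribution subsampling
    """

    family: str = "random_forest"
    n_trees: int = 200
    min_weight_fraction_leaf: float = 0.0
    C: float = 1.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be positive")
        if not 0 <= self.min_weight_fraction_leaf < 0.5:
            raise ValueError("min_weight_fraction_leaf must be in [0, 0.5)")
        if self.C <= 0:
            raise ValueError("C must be positive")


@dataclass
class ImportanceVector:
    """Nonnegative per-column importances, sum-normalized to 1."""

    importances: np.ndarray
    source: str = "tree_shapley"

    def __post_init__(self) -> None:
        imp = np.asarray(self.importances, dtype=float)
        if (imp < 0).any() or not np.isfinite(imp).all():
            raise ValueError("importances must be finite and nonnegative")
        total = imp.sum()
        if total <= 0:
            warnings.warn("all-zero importances; falling back to uniform")
            imp = np.full(len(imp), 1.0 / len(imp))
        else:
            imp = imp / total
        self.importances = imp

    def __array__(self, dtype=None, copy=None):
        return self.importances.astype(dtype) if dtype is not None else self.importances

    def __len__(self) -> int:
        return len(self.importances)


def _as_matrix(X) -> np.ndarray:
    values = getattr(X, "values", X)
    if callable(getattr(values, "to_numpy", None)):  # DataFrame
        values = values.to_numpy()
    return np.asarray(values, dtype=np.float64)


def train_domain_classifier(N, R, spec: DomainClassifierSpec):
    """Train the unweighted domain classifier: N labeled 0, R labeled 1.

    Uniform sample and feature weights; the classifier scores the estimated
    probability of a row belonging to the representative sample.
    """
    Xn, Xr = _as_matrix(N), _as_matrix(R)
    if len(Xn) == 0 or len(Xr) == 0:
        raise ValueError("both N and R must be non-empty")
    if Xn.shape[1] != Xr.shape[1]:
        raise ValueError("N and R must share the encoded feature space")
    X = np.vstack([Xn, Xr])
    y = np.concatenate([np.zeros(len(Xn), dtype=int), np.ones(len(Xr), dtype=int)])
    if spec.family == "random_forest":
        clf = RandomForestClassifier(
            n_estimators=spec.n_trees,
            min_weight_fraction_leaf=spec.min_weight_fraction_leaf,
            random_state=spec.random_seed,
            n_jobs=1,
        )
        clf.fit(X, y)
    else:
        clf = FeatureWeightedLinearSVM(C=spec.C, random_state=spec.random_seed)
        clf.fit(X, y)
    return clf


def estimate_importance(
    classifier,
    X,
    spec: DomainClassifierSpec,
    method: str | None = None,
    y=None,
    max_foreground: int = 200,
    max_background: int = 100,
) -> ImportanceVector:
    """Global per-column importance of the domain classifier on the pooled rows.

    method : "tree_shapley", "linear_shapley", "permutation" or None
        None picks the Shapley variant matching the classifier family.
        "tree_shapley" uses exact interventional tree-path attributions with
        the pooled rows (seeded subsample) as background; "linear_shapley"
        is the closed form |coef_j * (x_ij - mean_j)| averaged over rows;
        "permutation" is the mean AUROC drop over 5 shuffles, intended for
        large inputs.

    Rows are subsampled (seeded) to at most ``max_foreground`` explained rows
    and ``max_background`` background rows for the tree variant.
    """
    X = _as_matrix(X)
    rng = np.random.default_rng(spec.random_seed)
    if method is None:
        method = "tree_shapley" if spec.family == "random_forest" else "linear_shapley"

    if method == "tree_shapley":
        if not hasattr(classifier, "estimators_"):
            raise ValueError("tree_shapley needs a tree-ensemble classifier")
        fore = X if len(X) <= max_foreground else X[
            rng.choice(len(X), size=max_foreground, replace=False)]
        back = X if len(X) <= max_background else X[
            rng.choice(len(X), size=max_background, replace=False)]
        phi = forest_interventional_shap(classifier.estimators_, fore, back)
        raw = np.abs(phi).mean(axis=0)
    elif method == "linear_shapley":
        coef = np.asarray(getattr(classifier, "coef_")).ravel()
        phi = coef * (X - X.mean(axis=0))
        raw = np.abs(phi).mean(axis=0)
    elif method == "permutation":
        if y is None:
            raise ValueError("permutation importance requires the domain labels y")
        return permutation_importance(classifier, X, y, spec)
    else:
        raise ValueError(f"unknown importance method {method!r}")
    return ImportanceVector(raw, source=method)


def permutation_importance(classifier, X, y, spec: DomainClassifierSpec,
                           n_shuffles: int = 5) -> ImportanceVector:
    """Mean AUROC drop when each column is shuffled (fallback for large inputs)."""
    X = _as_matrix(X)
    y = np.asarray(y)
    rng = np.random.default_rng(spec.random_seed)
    base = auroc(classifier.predict_proba(X)[:, 1], y)
    raw = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        drops = []
        for _ in range(n_shuffles):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(X)), j]
            drops.append(base - auroc(classifier.predict_proba(Xp)[:, 1], y))
        raw[j] = max(np.mean(drops), 0.0)
    return ImportanceVector(raw, source="permutation")


def softmin_weights(I, t: float) -> FeatureWeights:
    """Softmin transformation of importances into feature weights at temperature t.

    Computed with max-shift stabilization; exact uniform input maps to exact
    uniform output, and as t -> 0 the weight concentrates on the argmin
    (ties split equally).
    """
    if not t > 0:
        raise ValueError(f"temperature must be positive, got {t}")
    imp = np.asarray(I, dtype=np.float64)
    logits = -imp / t
    logits -= logits.max()
    w = np.exp(logits)
    w /= w.sum()
    # floor to keep weights strictly positive (simplex invariant) even when
    # exp underflows at extreme peaking
    tiny = np.finfo(float).tiny
    if (w <= 0).any():
        w = np.maximum(w, tiny)
        w /= w.sum()
    return FeatureWeights(w, temperature=float(t))
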