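"""Classifiers that honor both sample weights and feature weights.

Two learner families are used throughout the debiasing loop and the
downstream task: a random forest whose split-candidate features are drawn
with probability proportional to the feature weights, and a linear SVM that
scales input columns by the feature weights.  Rows with sample weight zero
(dropped samples) are excluded from training; remaining sample weights enter
the impurity / loss directly.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "WeightedRandomForestClassifier",
    "FeatureWeightedLinearSVM",
    "auroc",
    "SingleClassError",
    "fit_weighted_forest",
    "fit_weighted_linear_svm",
]


class SingleClassError(ValueError):
    """Raised when an operation needs both classes but only one is present."""


def _check_weights(n, sample_weight, feature_weight, p):
    sw = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    if sw.shape != (n,):
        raise ValueError(f"sample_weight has shape {sw.shape}, expected ({n},)")
    if (sw < 0).any():
        raise ValueError("sample weights must be nonnegative")
    if not (sw > 0).any():
        raise ValueError("all sample weights are zero")
    fw = np.full(p, 1.0 / p) if feature_weight is None else np.asarray(feature_weight, dtype=float)
    if fw.shape != (p,):
        raise ValueError(f"feature_weight has shape {fw.shape}, expected ({p},)")
    if (fw < 0).any():
        raise ValueError("feature weights must be nonnegative")
    if not (fw > 0).any():
        raise ValueError("all feature weights are zero")
    return sw, fw


def _weighted_subset(rng: np.random.Generator, weights: np.ndarray, size: int) -> np.ndarray:
    """Draw ``size`` indices without replacement, sequentially proportional to
    ``weights`` renormalized over the not-yet-drawn indices (Gumbel top-k)."""
    pos = weights > 0
    logw = np.full(len(weights), -np.inf)
    logw[pos] = np.log(weights[pos])
    keys = logw + rng.gumbel(size=len(weights))
    size = min(size, int(pos.sum()))
    return np.sort(np.argpartition(-keys, size - 1)[:size])


class WeightedRandomForestClassifier(ClassifierMixin, BaseEstimator):
    """Random forest with feature-weight-proportional split-candidate sampling.

    Each tree draws its candidate feature set once, without replacement and
    with probability proportional to the feature weights, and considers
    exactly that set at every split.  Zero-weight features are never
    candidates; sample weights are passed to the underlying trees, entering
    impurity and leaf estimates.

    Parameters
    ----------
    n_estimators : int, default 200
        Number of trees.
    min_weight_fraction_leaf : float, default 0.0
        Minimum weighted fraction of the total sample weight in a leaf.
    max_candidate_features : int, "sqrt" or None, default "sqrt"
        Size of each tree's candidate feature set ("sqrt" gives
        ``ceil(sqrt(p_positive))``; None uses all positive-weight features).
    bootstrap : bool, default True
    random_state : int or None
    """

    def __init__(self, n_estimators=200, min_weight_fraction_leaf=0.0,
                 max_candidate_features="sqrt", bootstrap=True, random_state=None):
        self.n_estimators = n_estimators
        self.min_weight_fraction_leaf = min_weight_fraction_leaf
        self.max_candidate_features = max_candidate_features
        self.bootstrap = bootstrap
        self.random_state = random_state

    def _candidate_size(self, n_positive: int) -> int:
        m = self.max_candidate_features
        if m is None:
            return n_positive
        if m == "sqrt":
            return int(np.ceil(np.sqrt(n_positive)))
        m = int(m)
        if m < 1:
            raise ValueError("max_candidate_features must be >= 1")
        return min(m, n_positive)

    def fit(self, X, y, sample_weight=None, feature_weight=None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        n, p = X.shape
        sw, fw = _check_weights(n, sample_weight, feature_weight, p)
        active = sw > 0
        Xa, ya, swa = X[active], y[active], sw[active]
        self.classes_ = np.unique(ya)
        rng = np.random.default_rng(self.random_state)
        size = self._candidate_size(int((fw > 0).sum()))
        self.estimators_ = []
        self.feature_subsets_ = []
        for _ in range(self.n_estimators):
            feats = _weighted_subset(rng, fw, size)
            if self.bootstrap:
                idx = rng.integers(0, len(Xa), size=len(Xa))
            else:
                idx = np.arange(len(Xa))
            tree = DecisionTreeClassifier(
                max_features=None,
                min_weight_fraction_leaf=self.min_weight_fraction_leaf,
                random_state=int(rng.integers(2**31)),
            )
            tree.fit(Xa[np.ix_(idx, feats)], ya[idx], sample_weight=swa[idx])
            self.estimators_.append(tree)
            self.feature_subsets_.append(feats)
        self.n_features_in_ = p
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=np.float64)
        proba = np.zeros((len(X), len(self.classes_)))
        for tree, feats in zip(self.estimators_, self.feature_subsets_):
            pt = tree.predict_proba(X[:, feats])
            cols = np.searchsorted(self.classes_, tree.classes_)
            proba[:, cols] += pt
        proba /= len(self.estimators_)
        return proba

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def used_features(self) -> np.ndarray:
        """Set of original column indices that appear in any split of any tree."""
        used = set()
        for tree, feats in zip(self.estimators_, self.feature_subsets_):
            split_cols = tree.tree_.feature
            used.update(feats[f] for f in split_cols[split_cols >= 0])
        return np.array(sorted(used), dtype=int)


class FeatureWeightedLinearSVM(ClassifierMixin, BaseEstimator):
    """l2-regularized linear SVM on feature-weight-scaled columns.

    The training (and prediction) matrix is ``X @ diag(feature_weight)``,
    so a zero-weight column contributes nothing to any decision value.
    Probabilities come from a Platt-style sigmoid fitted on the training
    decision values — a monotone calibration, so rankings are unaffected.

    Expects standardized inputs (the scaling interacts with regularization).
    """

    def __init__(self, C=1.0, random_state=None, max_iter=5000):
        self.C = C
        self.random_state = random_state
        self.max_iter = max_iter

    def fit(self, X, y, sample_weight=None, feature_weight=None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        n, p = X.shape
        sw, fw = _check_weights(n, sample_weight, feature_weight, p)
        active = sw > 0
        Xa, ya, swa = X[active], y[active], sw[active]
        self.classes_ = np.unique(ya)
        if len(self.classes_) < 2:
            raise SingleClassError("linear SVM needs both classes among active rows")
        self.feature_weight_ = fw
        self._svm = LinearSVC(C=self.C, random_state=self.random_state,
                              max_iter=self.max_iter)
        self._svm.fit(Xa * fw, ya, sample_weight=swa)
        scores = self._svm.decision_function(Xa * fw)
        # Platt-style monotone sigmoid on training scores (light l2 keeps the
        # fit finite on separable data; calibration only affects probability
        # scale, never ranking)
        self._platt = LogisticRegression(C=1e4, max_iter=1000)
        self._platt.fit(scores.reshape(-1, 1), ya, sample_weight=swa)
        self.coef_ = self._svm.coef_ * fw  # effective coefficients on raw columns
        self.intercept_ = self._svm.intercept_
        self.n_features_in_ = p
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=np.float64)
        return self._svm.decision_function(X * self.feature_weight_)

    def predict_proba(self, X):
        s = self.decision_function(X).reshape(-1, 1)
        return self._platt.predict_proba(s)

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


def auroc(scores, labels, sample_weight=None) -> float:
    """Weighted probability that a random positive outranks a random negative.

    Ties count one half.  Raises :class:`SingleClassError` when only one
    class has positive weight (callers typically skip such folds).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if sample_weight is not None:
        sample_weight = np.asarray(sample_weight, dtype=float)
        mask = sample_weight > 0
    else:
        mask = np.ones(len(labels), dtype=bool)
    present = np.unique(labels[mask])
    if len(present) < 2:
        raise SingleClassError("AUROC undefined: a single class among weighted rows")
    return float(roc_auc_score(labels, scores, sample_weight=sample_weight))


def fit_weighted_forest(X, y, sample_w=None, feature_w=None, **config):
    """Functional wrapper over :class:`WeightedRandomForestClassifier`."""
    return WeightedRandomForestClassifier(**config).fit(
        X, y, sample_weight=np.asarray(sample_w) if sample_w is not None else None,
        feature_weight=np.asarray(feature_w) if feature_w is not None else None)


def fit_weighted_linear_svm(X, y, sample_w=None, feature_w=None, **config):
    """Functional wrapper over :class:`FeatureWeightedLinearSVM`."""
    return FeatureWeightedLinearSVM(**config).fit(
        X, y, sample_weight=np.asarray(sample_w) if sample_w is not None else None,
        feature_weight=np.asarray(feature_w) if feature_w is not None else None)
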