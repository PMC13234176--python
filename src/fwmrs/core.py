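"""The iterative feature-weighted maximum representative subsampling loop.

The algorithm aligns a non-representative sample N to a representative
reference R by repeatedly removing the N rows a feature- and sample-weighted
domain classifier is most confident are non-representative:

1. initialize all N sample weights to 1;
2. train an *unweighted* domain classifier on N (label 0) vs R (label 1),
   compute feature importances, and convert them once to feature weights via
   softmin at temperature t;
3. loop: if the number of still-active N rows does not exceed the per-
   iteration drop count d, declare the bias infeasible to mitigate and
   return no weights; otherwise run k-fold cross-validation over the pooled
   active N and R rows (positive-unlabeled framing: R positive, N treated as
   negative), storing each fold's held-out scores; if the fold-mean AUROC is
   no better than chance (<= 0.5), stop and return the current weights; else
   zero the weights of the d active rows with the lowest out-of-fold
   representativeness score and repeat.

Plain maximum representative subsampling is the special case with exactly
uniform feature weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold

from .data_model import Dataset, FeatureWeights, SampleWeights
from .feature_weighting import (
    DomainClassifierSpec,
    estimate_importance,
    softmin_weights,
    train_domain_classifier,
)
from .weighted_learners import (
    FeatureWeightedLinearSVM,
    SingleClassError,
    WeightedRandomForestClassifier,
    auroc,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FWMRSConfig",
    "DebiasResult",
    "IterationRecord",
    "IterationLimitError",
    "FWMRS",
    "run_fwmrs",
    "cv_round",
]


class IterationLimitError(RuntimeError):
    """The loop exceeded ``max_iterations`` (distinct from infeasibility)."""


@dataclass
class FWMRSConfig:
    """Loop configuration.

    n_folds : cross-validation splits k (default 5)
    drop_per_iteration : samples removed per iteration d (default 1)
    temperature : softmin temperature t
    classifier : domain classifier spec (family, size, regularization, seed)
    auroc_stop_threshold : stop when fold-mean AUROC <= this (default 0.5)
    max_iterations : guard; None means the attrition bound
    """

    n_folds: int = 5
    drop_per_iteration: int = 1
    temperature: float = 0.05
    classifier: DomainClassifierSpec = field(default_factory=DomainClassifierSpec)
    auroc_stop_threshold: float = 0.5
    random_seed: int = 0
    max_iterations: int | None = None

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.drop_per_iteration < 1:
            raise ValueError("drop_per_iteration must be >= 1")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")


@dataclass
class IterationRecord:
    iteration: int
    mean_auroc: float
    dropped_indices: list[int]


@dataclass
class DebiasResult:
    """Outcome of a debiasing run.

    ``status`` is "converged" or "infeasible"; on infeasibility no sample or
    feature weights are returned (both None) — only the trace is kept.
    """

    status: str
    sample_weights: SampleWeights | None
    feature_weights: FeatureWeights | None
    trace: list[IterationRecord]

    @property
    def n_dropped(self) -> int:
        return sum(len(r.dropped_indices) for r in self.trace)

    def trace_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": [r.iteration for r in self.trace],
                "mean_auroc": [r.mean_auroc for r in self.trace],
                "n_dropped_total": np.cumsum(
                    [len(r.dropped_indices) for r in self.trace]
                ),
            }
        )


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, Dataset):
        return X.values
    values = getattr(X, "values", X)
    if callable(getattr(values, "to_numpy", None)):
        values = values.to_numpy()
    return np.asarray(values, dtype=np.float64)


def cv_round(
    N_active: np.ndarray,
    R: np.ndarray,
    feature_w,
    cfg: FWMRSConfig,
    seed: int,
):
    """One PU-learning CV round of the weighted domain classifier.

    Pools the active N rows (label 0, treated as negative/unlabeled) with all
    of R (label 1, positive), splits into ``cfg.n_folds`` folds stratified by
    source with a seeded shuffle, trains the feature-weighted classifier on
    k-1 folds and scores the held-out fold.  Returns the fold-mean AUROC and
    the out-of-fold representativeness score of every active N row.

    Folds whose hold-out lacks one source are skipped from the mean (logged);
    if every fold is skipped an error is raised.
    """
    N_active = np.asarray(N_active, dtype=float)
    R = np.asarray(R, dtype=float)
    if len(N_active) == 0 or len(R) == 0:
        raise ValueError("both N_active and R must be non-empty")
    fw = np.asarray(feature_w, dtype=float)
    X = np.vstack([N_active, R])
    y = np.concatenate([np.zeros(len(N_active), dtype=int), np.ones(len(R), dtype=int)])
    n_splits = min(cfg.n_folds, len(N_active), len(R))
    if n_splits < 2:
        n_splits = 2
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)
    oof = np.full(len(N_active), np.nan)
    fold_aurocs = []
    for train_idx, test_idx in skf.split(X, y):
        if cfg.classifier.family == "random_forest":
            clf = WeightedRandomForestClassifier(
                n_estimators=cfg.classifier.n_trees,
                min_weight_fraction_leaf=cfg.classifier.min_weight_fraction_leaf,
                random_state=int(rng.integers(2**31)),
            )
        else:
            clf = FeatureWeightedLinearSVM(
                C=cfg.classifier.C, random_state=int(rng.integers(2**31))
            )
        try:
            clf.fit(X[train_idx], y[train_idx], feature_weight=fw)
            scores = clf.predict_proba(X[test_idx])[:, 1]
            fold_aurocs.append(auroc(scores, y[test_idx]))
        except SingleClassError:
            logger.info("skipping fold with a single source in train or hold-out")
            continue
        n_mask = test_idx < len(N_active)
        oof[test_idx[n_mask]] = scores[n_mask]
    if not fold_aurocs:
        raise ValueError("every cross-validation fold lacked one source")
    return float(np.mean(fold_aurocs)), oof


class FWMRS(BaseEstimator):
    """Feature-weighted maximum representative subsampling.

    A debiasing estimator in the sklearn idiom: ``fit(N, R)`` runs the
    iterative loop and exposes the result as fitted attributes.

    Parameters
    ----------
    temperature : float, default 0.05
        Softmin temperature t; lower values concentrate feature weight on
        the least biased features so fewer samples must be dropped.
    classifier : {"random_forest", "linear_svm"}, default "random_forest"
    n_trees : int, default 200
        Domain-forest size (forest family).
    min_weight_fraction_leaf : float, default 0.0
    C : float, default 1.0
        SVM regularization (SVM family).
    importance : str or None
        Importance method override (None = Shapley variant of the family).
    n_folds : int, default 5
    drop_per_iteration : int, default 1
    auroc_stop_threshold : float, default 0.5
    max_iterations : int or None
    random_state : int or None

    Attributes
    ----------
    sample_weights_ : ndarray or None
        Binary per-row weights over N (1 active, 0 dropped); None if
        infeasible.
    feature_weights_ : FeatureWeights or None
    trace_ : list of IterationRecord
    status_ : "converged" or "infeasible"
    result_ : DebiasResult
    """

    _uniform_feature_weights = False  # subclass hook (plain MRS)

    def __init__(self, temperature=0.05, classifier="random_forest", n_trees=200,
                 min_weight_fraction_leaf=0.0, C=1.0, importance=None, n_folds=5,
                 drop_per_iteration=1, auroc_stop_threshold=0.5, max_iterations=None,
                 random_state=None):
        self.temperature = temperature
        self.classifier = classifier
        self.n_trees = n_trees
        self.min_weight_fraction_leaf = min_weight_fraction_leaf
        self.C = C
        self.importance = importance
        self.n_folds = n_folds
        self.drop_per_iteration = drop_per_iteration
        self.auroc_stop_threshold = auroc_stop_threshold
        self.max_iterations = max_iterations
        self.random_state = random_state

    def _config(self) -> FWMRSConfig:
        seed = 0 if self.random_state is None else int(self.random_state)
        return FWMRSConfig(
            n_folds=self.n_folds,
            drop_per_iteration=self.drop_per_iteration,
            temperature=self.temperature,
            classifier=DomainClassifierSpec(
                family=self.classifier,
                n_trees=self.n_trees,
                min_weight_fraction_leaf=self.min_weight_fraction_leaf,
                C=self.C,
                random_seed=seed,
            ),
            auroc_stop_threshold=self.auroc_stop_threshold,
            random_seed=seed,
            max_iterations=self.max_iterations,
        )

    def _initial_feature_weights(self, Xn, Xr, cfg) -> FeatureWeights:
        if self._uniform_feature_weights:
            return FeatureWeights.uniform(Xn.shape[1])
        clf = train_domain_classifier(Xn, Xr, cfg.classifier)
        pooled = np.vstack([Xn, Xr])
        y = np.concatenate([np.zeros(len(Xn), dtype=int), np.ones(len(Xr), dtype=int)])
        imp = estimate_importance(clf, pooled, cfg.classifier,
                                  method=self.importance, y=y)
        self.importances_ = imp
        return softmin_weights(imp, cfg.temperature)

    def fit(self, N, R):
        Xn, Xr = _as_matrix(N), _as_matrix(R)
        if Xn.ndim != 2 or Xr.ndim != 2 or Xn.shape[1] != Xr.shape[1]:
            raise ValueError("N and R must be 2-D with a shared encoded space")
        cfg = self._config()
        d = cfg.drop_per_iteration
        if len(Xn) <= d:
            raise ValueError("N must contain more rows than drop_per_iteration")
        fw = self._initial_feature_weights(Xn, Xr, cfg)
        weights = np.ones(len(Xn))
        rng = np.random.default_rng(cfg.random_seed)
        attrition_bound = (len(Xn) - 1) // d + 1
        max_iter = cfg.max_iterations if cfg.max_iterations is not None else attrition_bound
        trace: list[IterationRecord] = []
        status = None
        for it in range(max_iter + 1):
            if it == max_iter and cfg.max_iterations is not None:
                raise IterationLimitError(
                    f"no convergence within {max_iter} iterations")
            active_idx = np.flatnonzero(weights > 0)
            if len(active_idx) <= d:
                status = "infeasible"
                logger.warning(
                    "bias cannot be sufficiently mitigated: %d active rows <= d=%d",
                    len(active_idx), d)
                break
            seed = int(rng.integers(2**31))
            mean_auroc, oof = cv_round(Xn[active_idx], Xr, fw, cfg, seed)
            if mean_auroc <= cfg.auroc_stop_threshold:
                trace.append(IterationRecord(it, mean_auroc, []))
                status = "converged"
                break
            # drop the d lowest-scoring rows; stable sort breaks ties by
            # ascending row index (active_idx is ascending)
            order = np.argsort(oof, kind="stable")
            dropped = active_idx[order[:d]]
            weights[dropped] = 0.0
            trace.append(IterationRecord(it, mean_auroc, [int(i) for i in dropped]))
        if status is None:
            raise IterationLimitError("attrition bound exhausted without a verdict")
        if status == "infeasible":
            self.result_ = DebiasResult("infeasible", None, None, trace)
            self.sample_weights_ = None
            self.feature_weights_ = None
        else:
            self.result_ = DebiasResult(
                "converged", SampleWeights(weights), fw, trace)
            self.sample_weights_ = weights
            self.feature_weights_ = fw
        self.trace_ = trace
        self.status_ = status
        return self


def run_fwmrs(N, R, cfg: FWMRSConfig,
              feature_weights_override: FeatureWeights | None = None) -> DebiasResult:
    """Functional wrapper over :class:`FWMRS` driven by an :class:`FWMRSConfig`.

    ``feature_weights_override`` replaces the importance-derived softmin
    weights (the exact-uniform override recovers plain subsampling).
    """
    est = FWMRS(
        temperature=cfg.temperature,
        classifier=cfg.classifier.family,
        n_trees=cfg.classifier.n_trees,
        min_weight_fraction_leaf=cfg.classifier.min_weight_fraction_leaf,
        C=cfg.classifier.C,
        n_folds=cfg.n_folds,
        drop_per_iteration=cfg.drop_per_iteration,
        auroc_stop_threshold=cfg.auroc_stop_threshold,
        max_iterations=cfg.max_iterations,
        random_state=cfg.random_seed,
    )
    if feature_weights_override is not None:
        override = FeatureWeights(np.asarray(feature_weights_override),
                                  getattr(feature_weights_override, "temperature", float("inf")))
        est._initial_feature_weights = lambda Xn, Xr, c: override  # type: ignore[method-assign]
    est.fit(N, R)
    return est.result_
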