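"""Synthetic populations, artificial bias injection, and the benchmark harness.

The generator emulates the structure of the tabular survey datasets the
method targets: a population with mixed numeric/categorical demographic
features and a binary outcome following a logistic model in a subset of the
numeric features.  Artificial selection bias is injected by undersampling
the positive outcome class to a retained fraction (default 10%), which makes
exactly the outcome-predictive features distribution-shifted — mirroring
real scenarios such as underdiagnosed medical conditions — while leaving the
non-predictive features approximately representative.

The harness reproduces the experimental protocol: 5-fold cross-validation
where each training set is split 50/50 into a biased non-representative half
N (keeping its outcome) and an untouched representative half R (outcome
structurally withheld), with the test fold T kept apart; debiasing methods
are compared by downstream weighted-forest AUROC on T, dropped-sample
fraction, and weighted MMD, with the corrected repeated-CV t-test and
Benjamini-Hochberg adjustment for significance.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .baselines import (
    MRS,
    KernelMeanMatching,
    PropensityScoreAdjustment,
    UniformWeighting,
)
from .core import FWMRS
from .data_model import Dataset, FeatureWeights, TableEncoder
from .metrics import (
    PairedScoreSeries,
    corrected_cv_ttest,
    heuristic_sigma,
    weighted_mmd,
)
from .weighted_learners import WeightedRandomForestClassifier, auroc

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationSpec",
    "BiasSpec",
    "ExperimentPlan",
    "generate_population",
    "inject_bias",
    "make_split",
    "run_experiment",
    "temperature_sweep",
]

TEMPERATURE_GRID = (0.001, 0.0025, 0.005, 0.01, 0.025, 0.05, 0.1, 0.25, 0.5)
MIN_WEIGHT_FRACTION_LEAF_GRID = (0.025, 0.01, 0.001, 0.0)
C_GRID = (1e-2, 1e-1, 1.0, 1e1, 1e2)


@dataclass
class PopulationSpec:
    """A synthetic survey population.

    Numeric features are standard Gaussian, categorical features multinomial
    (uniform over levels).  The binary outcome follows a logistic model in
    the numeric features with coefficients ``outcome_coefficients`` (default
    (1.5, 1.0, 0.5) padded with zeros: some features predictive — and hence
    biased after positive-class undersampling — others representative).
    ``shifts``/``scales`` are per-numeric-feature location/scale knobs applied
    only when drawing the shifted sub-population, for fixtures with known
    distribution-shifted features.
    """

    n_numeric: int = 5
    n_categorical: int = 0
    n_category_levels: int = 3
    outcome_coefficients: tuple | None = None
    intercept: float = 0.0
    shifts: tuple | None = None
    scales: tuple | None = None

    def __post_init__(self) -> None:
        if self.n_numeric + self.n_categorical < 1:
            raise ValueError("need at least one feature")
        if self.n_categorical and self.n_category_levels < 2:
            raise ValueError("categorical features need at least two levels")
        if self.outcome_coefficients is None:
            base = (1.5, 1.0, 0.5)
            self.outcome_coefficients = tuple(
                base[i] if i < len(base) else 0.0 for i in range(self.n_numeric))
        if len(self.outcome_coefficients) != self.n_numeric:
            raise ValueError("one outcome coefficient per numeric feature")
        if self.shifts is not None and len(self.shifts) != self.n_numeric:
            raise ValueError("one shift per numeric feature")
        if self.scales is not None and len(self.scales) != self.n_numeric:
            raise ValueError("one scale per numeric feature")


@dataclass
class BiasSpec:
    """Positive-class undersampling: retain fraction rho of positive rows."""

    retained_fraction: float = 0.10
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.retained_fraction <= 1:
            raise ValueError("retained_fraction must be in (0, 1]")


def generate_population(spec: PopulationSpec, n: int, seed: int = 0,
                        shifted: bool = False, role: str = "test") -> Dataset:
    """Draw ``n`` rows from the population (seeded, deterministic).

    ``shifted=True`` applies the spec's per-feature shift/scale knobs —
    the mechanism for fixtures where selected features differ between
    sub-populations.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    Xnum = rng.standard_normal((n, spec.n_numeric))
    logits = spec.intercept + Xnum @ np.asarray(spec.outcome_coefficients)
    outcome = (rng.random(n) < expit(logits)).astype(np.int64)
    if shifted:
        if spec.scales is not None:
            Xnum = Xnum * np.asarray(spec.scales)
        if spec.shifts is not None:
            Xnum = Xnum + np.asarray(spec.shifts)
    cols = {f"x{i}": Xnum[:, i] for i in range(spec.n_numeric)}
    for j in range(spec.n_categorical):
        draws = rng.integers(0, spec.n_category_levels, size=n)
        cols[f"c{j}"] = pd.Categorical.from_codes(
            draws, categories=[f"level{k}" for k in range(spec.n_category_levels)]
        ).astype(str)
    return Dataset(pd.DataFrame(cols), outcome, role)


def inject_bias(data: Dataset, spec: BiasSpec) -> Dataset:
    """Undersample the positive class to ``retained_fraction``, keeping all
    negatives; row order is preserved."""
    if data.outcome is None:
        raise ValueError("bias injection requires an outcome")
    pos = np.flatnonzero(data.outcome == 1)
    if len(pos) == 0:
        raise ValueError("no positive rows to undersample")
    n_keep = int(np.ceil(spec.retained_fraction * len(pos)))
    rng = np.random.default_rng(spec.random_seed)
    kept_pos = rng.choice(pos, size=n_keep, replace=False)
    keep = np.sort(np.concatenate([np.flatnonzero(data.outcome == 0), kept_pos]))
    return data.subset(keep)


def make_split(data: Dataset, repeat_seed: int, fold: int, n_folds: int = 5,
               bias: BiasSpec | None = None, return_clean: bool = False):
    """One (N, R, T) split of the evaluation protocol.

    The data is partitioned into ``n_folds`` folds (seeded by
    ``repeat_seed``); fold ``fold`` is the untouched test set T.  The
    remaining training rows are shuffled and split 50/50: one half receives
    the bias injection and becomes N (keeping its outcome), the other half
    becomes the representative reference R with its outcome withheld.
    """
    if data.outcome is None:
        raise ValueError("the protocol requires an outcome")
    n = data.n_samples
    if n < n_folds:
        raise ValueError("fewer rows than folds")
    if not 0 <= fold < n_folds:
        raise ValueError(f"fold must be in [0, {n_folds})")
    rng = np.random.default_rng(repeat_seed)
    perm = rng.permutation(n)
    bounds = np.linspace(0, n, n_folds + 1).astype(int)
    test_idx = np.sort(perm[bounds[fold]:bounds[fold + 1]])
    train_idx = np.sort(np.setdiff1d(perm, test_idx))
    half_rng = np.random.default_rng((repeat_seed, fold))
    shuffled = half_rng.permutation(train_idx)
    half = len(shuffled) // 2
    n_idx, r_idx = np.sort(shuffled[:half]), np.sort(shuffled[half:])
    bias = bias or BiasSpec(random_seed=int(half_rng.integers(2**31)))
    N_clean = data.subset(n_idx).with_role("nonrepresentative")
    N = inject_bias(N_clean, bias)
    R_full = data.subset(r_idx)
    R = Dataset(R_full.table, None, "representative")  # outcome withheld
    T = data.subset(test_idx).with_role("test")
    if return_clean:
        return N, R, T, N_clean
    return N, R, T


@dataclass
class ExperimentPlan:
    """The benchmark protocol and hyperparameter grids.

    Defaults follow the evaluation protocol: 10 repeats of 5-fold CV, a
    6000-row subsample cap, 5 samples dropped per iteration on large
    datasets (1 on small), a 500-tree downstream weighted forest, a 200-tree
    domain forest, and grid search by cross-validation AUROC over N.
    """

    n_repeats: int = 10
    n_folds: int = 5
    subsample_cap: int = 6000
    drop_large: int = 5
    drop_small: int = 1
    methods: tuple = ("uniform", "kmm", "psa", "mrs", "fwmrs_rf", "fwmrs_svm")
    temperature_grid: tuple = TEMPERATURE_GRID
    min_weight_fraction_leaf_grid: tuple = MIN_WEIGHT_FRACTION_LEAF_GRID
    C_grid: tuple = C_GRID
    downstream_trees: int = 500
    domain_trees: int = 200
    selection_folds: int = 5
    include_unbiased: bool = True
    bias: BiasSpec = field(default_factory=BiasSpec)
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1 or self.n_folds < 2:
            raise ValueError("need n_repeats >= 1 and n_folds >= 2")
        for g in (self.temperature_grid, self.min_weight_fraction_leaf_grid, self.C_grid):
            if len(g) == 0:
                raise ValueError("hyperparameter grids must be non-empty")
        unknown = set(self.methods) - {
            "uniform", "kmm", "psa", "mrs", "fwmrs_rf", "fwmrs_svm"}
        if unknown:
            raise ValueError(
                f"unknown methods {sorted(unknown)}; valid: uniform, kmm, psa, "
                "mrs, fwmrs_rf, fwmrs_svm")


def _method_grid(method: str, plan: ExperimentPlan):
    if method == "fwmrs_rf":
        return [{"temperature": t, "min_weight_fraction_leaf": mw}
                for t, mw in itertools.product(
                    plan.temperature_grid, plan.min_weight_fraction_leaf_grid)]
    if method == "fwmrs_svm":
        return [{"temperature": t, "C": c}
                for t, c in itertools.product(plan.temperature_grid, plan.C_grid)]
    if method == "mrs":
        return [{"min_weight_fraction_leaf": mw}
                for mw in plan.min_weight_fraction_leaf_grid]
    if method == "psa":
        return [{"C": c} for c in plan.C_grid]
    return [{}]


def _debias(method: str, params: dict, N_enc_std, N_enc_raw, R_enc_std, R_enc_raw,
            plan: ExperimentPlan, d: int, seed: int):
    """Run one debiasing method; returns (sample_w, feature_w, status, n_dropped)."""
    p = N_enc_raw.shape[1]
    if method == "uniform":
        est = UniformWeighting().fit(N_enc_raw)
        return est.sample_weights_, est.feature_weights_, "converged", 0
    if method == "kmm":
        est = KernelMeanMatching().fit(N_enc_std, R_enc_std)
        return est.sample_weights_, FeatureWeights.uniform(p), "converged", 0
    if method == "psa":
        est = PropensityScoreAdjustment(C=params.get("C", 1.0), random_state=seed)
        est.fit(N_enc_std, R_enc_std)
        return est.sample_weights_, FeatureWeights.uniform(p), "converged", 0
    if method == "mrs":
        est = MRS(n_trees=plan.domain_trees,
                  min_weight_fraction_leaf=params.get("min_weight_fraction_leaf", 0.0),
                  drop_per_iteration=d, random_state=seed)
        est.fit(N_enc_raw, R_enc_raw)
    elif method == "fwmrs_rf":
        est = FWMRS(temperature=params["temperature"],
                    classifier="random_forest", n_trees=plan.domain_trees,
                    min_weight_fraction_leaf=params.get("min_weight_fraction_leaf", 0.0),
                    drop_per_iteration=d, random_state=seed)
        est.fit(N_enc_raw, R_enc_raw)
    else:  # fwmrs_svm
        est = FWMRS(temperature=params["temperature"], classifier="linear_svm",
                    C=params.get("C", 1.0), drop_per_iteration=d, random_state=seed)
        est.fit(N_enc_std, R_enc_std)
    if est.status_ == "infeasible":
        return None, None, "infeasible", est.result_.n_dropped
    return (est.sample_weights_, est.feature_weights_, "converged",
            est.result_.n_dropped)


def _downstream_cv_auroc(Xn, y, sample_w, feature_w, plan: ExperimentPlan,
                         seed: int, n_trees: int | None = None) -> float:
    """Weighted-forest CV AUROC over N — the model-selection criterion."""
    from sklearn.model_selection import StratifiedKFold

    active = sample_w > 0
    Xa, ya, wa = Xn[active], y[active], sample_w[active]
    k = min(plan.selection_folds, np.bincount(ya).min())
    if k < 2:
        return np.nan
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = []
    for tr, te in skf.split(Xa, ya):
        clf = WeightedRandomForestClassifier(
            n_estimators=n_trees or plan.downstream_trees, random_state=seed)
        clf.fit(Xa[tr], ya[tr], sample_weight=wa[tr], feature_weight=np.asarray(feature_w))
        try:
            scores.append(auroc(clf.predict_proba(Xa[te])[:, 1], ya[te]))
        except Exception:
            continue
    return float(np.mean(scores)) if scores else np.nan


def run_experiment(data: Dataset, plan: ExperimentPlan) -> dict:
    """The full benchmark: repeats x folds x methods with grid selection.

    For every repeat and fold, N/R/T are constructed, each method's
    hyperparameters are selected by weighted-forest CV AUROC over N
    (debiasing re-run per grid point), the downstream forest is fitted on
    all of N with the selected sample and feature weights, and test AUROC on
    T, dropped fraction, and weighted MMD (N vs T, before and after) are
    recorded.  Returns per-run and summary tables plus the corrected t-test
    between the feature-weighted and plain subsampling arms.
    """
    if data.n_samples > plan.subsample_cap:
        rng = np.random.default_rng(plan.random_seed)
        data = data.subset(np.sort(rng.choice(
            data.n_samples, size=plan.subsample_cap, replace=False)))
    d = plan.drop_large if data.n_samples >= plan.subsample_cap else plan.drop_small
    rows = []
    master = np.random.default_rng(plan.random_seed)
    for rep in range(plan.n_repeats):
        rep_seed = int(master.integers(2**31))
        for fold in range(plan.n_folds):
            N, R, T, N_clean = make_split(data, rep_seed, fold, plan.n_folds,
                                          plan.bias, return_clean=True)
            enc = TableEncoder().fit([N, R])
            N_std, R_std = enc.transform(N).values, enc.transform(R).values
            N_raw = enc.transform(N, standardize=False).values
            R_raw = enc.transform(R, standardize=False).values
            T_std = enc.transform(T).values
            y = N.outcome
            sigma = heuristic_sigma(np.vstack([N_std, T_std]))
            fold_seed = int(np.random.default_rng((rep_seed, fold)).integers(2**31))
            for method in plan.methods:
                best = None
                for params in _method_grid(method, plan):
                    sw, fw, status, n_drop = _debias(
                        method, params, N_std, N_raw, R_std, R_raw, plan, d, fold_seed)
                    if status == "infeasible":
                        cand = (-np.inf, params, None, None, status, n_drop)
                    else:
                        sel = _downstream_cv_auroc(N_raw, y, sw, np.asarray(fw),
                                                   plan, fold_seed)
                        cand = (sel, params, sw, fw, status, n_drop)
                    if best is None or cand[0] > best[0]:
                        best = cand
                sel_auroc, params, sw, fw, status, n_drop = best
                if status == "infeasible":
                    rows.append(dict(method=method, repeat=rep, fold=fold,
                                     status="infeasible", test_auroc=np.nan,
                                     dropped_fraction=np.nan, mmd_pre=np.nan,
                                     mmd_post=np.nan))
                    continue
                clf = WeightedRandomForestClassifier(
                    n_estimators=plan.downstream_trees, random_state=fold_seed)
                clf.fit(N_raw, y, sample_weight=sw, feature_weight=np.asarray(fw))
                T_raw = enc.transform(T, standardize=False).values
                test_auroc = auroc(clf.predict_proba(T_raw)[:, 1], T.outcome)
                mmd_pre = weighted_mmd(N_std, T_std, w_f=np.asarray(fw), sigma=sigma)
                mmd_post = weighted_mmd(N_std, T_std, w_X=sw,
                                        w_f=np.asarray(fw), sigma=sigma)
                rows.append(dict(method=method, repeat=rep, fold=fold,
                                 status="converged", test_auroc=test_auroc,
                                 dropped_fraction=n_drop / len(N_raw),
                                 mmd_pre=mmd_pre, mmd_post=mmd_post))
            if plan.include_unbiased:
                # reference arm: downstream trained on the un-biased train half
                Nc_raw = enc.transform(N_clean, standardize=False).values
                T_raw = enc.transform(T, standardize=False).values
                clf = WeightedRandomForestClassifier(
                    n_estimators=plan.downstream_trees, random_state=fold_seed)
                clf.fit(Nc_raw, N_clean.outcome)
                rows.append(dict(
                    method="unbiased", repeat=rep, fold=fold, status="converged",
                    test_auroc=auroc(clf.predict_proba(T_raw)[:, 1], T.outcome),
                    dropped_fraction=0.0, mmd_pre=np.nan, mmd_post=np.nan))
    results = pd.DataFrame(rows)
    summary = (results[results.status == "converged"]
               .groupby("method")[["test_auroc", "dropped_fraction", "mmd_pre", "mmd_post"]]
               .agg(["mean", "std"]))
    out = {"runs": results, "summary": summary}
    have = set(results.method)
    if {"mrs", "fwmrs_rf"} <= have:
        a = results[results.method == "fwmrs_rf"].sort_values(["repeat", "fold"])
        b = results[results.method == "mrs"].sort_values(["repeat", "fold"])
        ok = a.status.eq("converged").to_numpy() & b.status.eq("converged").to_numpy()
        if ok.sum() >= 2:
            n = data.n_samples
            series = PairedScoreSeries(
                a.test_auroc.to_numpy()[ok], b.test_auroc.to_numpy()[ok],
                n_train=int(n * (plan.n_folds - 1) / plan.n_folds),
                n_test=int(n / plan.n_folds))
            t, pval = corrected_cv_ttest(series)
            out["fwmrs_vs_mrs"] = {"t": t, "p": pval}
    return out


def temperature_sweep(N, R, grid=TEMPERATURE_GRID, n_runs: int = 20,
                      T=None, include_mrs: bool = True, n_trees: int = 200,
                      drop_per_iteration: int = 1, n_folds: int = 5,
                      random_seed: int = 0, max_fraction_dropped: float = 1.0) -> pd.DataFrame:
    """Drop-count / MMD trade-off across softmin temperatures.

    Runs the feature-weighted loop once per (temperature, seed), with seeds
    shared across temperatures, and reports per-temperature mean and sd of
    dropped samples and of the weighted MMD between the reweighted N and the
    reference (T when given, else R).  ``include_mrs`` appends the
    uniform-feature-weight baseline row (the high-temperature limit).
    """
    if len(grid) == 0:
        raise ValueError("temperature grid must be non-empty")
    from .core import _as_matrix

    Xn, Xr = _as_matrix(N), _as_matrix(R)
    Xref = Xr if T is None else _as_matrix(T)
    sigma = heuristic_sigma(np.vstack([Xn, Xref]))
    seeds = [int(s) for s in
             np.random.default_rng(random_seed).integers(2**31, size=n_runs)]
    rows = []
    arms = ([("mrs", None)] if include_mrs else []) + [(f"{t}", t) for t in grid]
    for label, t in arms:
        drops, mmds, statuses = [], [], []
        for seed in seeds:
            if t is None:
                est = MRS(n_trees=n_trees, drop_per_iteration=drop_per_iteration,
                          n_folds=n_folds, random_state=seed)
            else:
                est = FWMRS(temperature=t, n_trees=n_trees,
                            drop_per_iteration=drop_per_iteration,
                            n_folds=n_folds, random_state=seed)
            est.fit(Xn, Xr)
            statuses.append(est.status_)
            if est.status_ != "converged":
                continue
            drops.append(est.result_.n_dropped)
            mmds.append(weighted_mmd(Xn, Xref, w_X=est.sample_weights_,
                                     w_f=np.asarray(est.feature_weights_),
                                     sigma=sigma))
        rows.append(dict(
            temperature=label,
            n_converged=len(drops),
            dropped_mean=float(np.mean(drops)) if drops else np.nan,
            dropped_sd=float(np.std(drops, ddof=1)) if len(drops) > 1 else np.nan,
            mmd_mean=float(np.mean(mmds)) if mmds else np.nan,
            mmd_sd=float(np.std(mmds, ddof=1)) if len(mmds) > 1 else np.nan,
        ))
    return pd.DataFrame(rows)
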