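# Methods

## The model

Two samples from the same population are given: a non-representative sample
`N` (carrying a binary downstream outcome) and a representative reference
`R` (no outcome). Bias is operationalized discriminatively: `N` is
representative exactly when a classifier trained to distinguish `N` from
`R` performs at chance. The subsampling loop therefore:

1. initializes all sample weights over `N` to 1 (weights stay binary
   throughout — 1 active, 0 dropped; no soft reweighting);
2. trains an *unweighted* domain classifier on all of `N` (label 0) vs `R`
   (label 1), computes per-feature importances, and converts them **once**
   to feature weights with the softmin `w_i ∝ exp(-I_i/t)`; they are never
   refreshed inside the loop;
3. iterates: the feature- and sample-weighted domain classifier is
   evaluated by k-fold cross-validation over the pooled active `N` ∪ `R`
   rows (positive–unlabeled framing: `R` positive, active `N` treated as
   negative). If the fold-mean AUROC is ≤ 0.5 the loop stops and returns
   the weights; otherwise the `d` active rows with the lowest out-of-fold
   representativeness score are zeroed. If ever the active count is ≤ `d`,
   the bias is declared infeasible to mitigate and *no* weights are
   returned.

Assumptions: `N` and `R` share a feature schema and population; a
representative subsample of `N` exists (otherwise the infeasible exit
fires); residual bias on features the softmin downweights is accepted in
exchange for retaining rows, which is the method's central trade-off.

## Design choices in detail

- **Stopping rule** — "no better than random" is implemented as
  `mean AUROC ≤ 0.5` (threshold configurable but deliberately not promoted
  as a user knob). Equality is included; finite-sample jitter makes the
  distinction immaterial.
- **CV design** — folds partition the pooled active `N` ∪ `R` rows,
  stratified by source with a seeded shuffle, so every fold's AUROC is
  computable; all of `R` participates. Drop ranking uses out-of-fold
  scores only. Folds whose hold-out lacks a source are skipped from the
  mean (logged); ties in drop scores break by ascending row index for
  determinism.
- **Importances** — the forest variant uses exact interventional Shapley
  attributions of P(representative), computed by enumerating the mixed
  x/z-consistent paths of each tree (a leaf reached under coalition
  constraints D_x, D_z contributes ±v·|D_x'|!·|D_z'|!/(|D_x|+|D_z|)! to the
  features involved). Attributions are averaged over a seeded background
  subsample (≤ 100 rows) of the pooled training matrix and over a seeded
  foreground subsample (≤ 200 rows); global importance is the mean absolute
  attribution, sum-normalized. The linear variant is the closed form
  |β_j (x_ij − x̄_j)| averaged over rows. Permutation importance (mean
  AUROC drop over 5 shuffles) is selectable for large inputs. An all-zero
  importance vector (classifier at chance) falls back to uniform weights
  with a warning, so the loop degrades to plain subsampling rather than
  erroring. Importances are normalized to the simplex *before* softmin:
  the standard temperature grid (0.001–0.5) only produces non-degenerate
  weights on that scale.
- **Weighted forest** — per-split weighted candidate sampling is realized
  per tree: each tree draws its candidate set once, without replacement,
  sequentially proportional to the feature weights (Gumbel top-k), and
  considers exactly that set at every split. This preserves the two
  testable properties of per-split sampling — zero-weight features never
  appear in any split, and candidate-selection frequencies are proportional
  to the weights — without re-implementing the tree grower. Sample weights
  pass into impurity and leaf estimates; bootstrap rows are drawn uniformly
  from the active rows.
- **Weighted SVM** — columns are scaled by `w` directly (not `√w`; both are
  monotone reparameterizations, and only the ranking matters for the drop
  step). Probabilities come from a Platt-style sigmoid fit on training
  decision values with a light l2 penalty to stay finite on separable data;
  the calibration is monotone, so drop rankings are unaffected.
- **Encoding** — one-hot with the union of category levels over all fitted
  datasets, z-scoring with pooled statistics (never per-dataset, since the
  whole point is to compare the two distributions). Kernel and linear
  methods receive standardized encodings; trees receive raw ones. Missing
  values are a hard error — imputation would silently alter the
  distributions being compared. Feature weights live on *encoded* columns;
  aggregating a categorical's member columns before softmin is possible
  upstream but not the default.
- **KMM** — the quadratic program uses B = 1000 and ε = (√n−1)/√n, with σ
  from the mean-pairwise-distance heuristic on the pooled rows; it is
  solved with a trust-region constrained optimizer on the (ridge-
  regularized) Gram matrix. Weights are passed downstream raw; they are
  normalized only inside the MMD.
- **Weighted MMD** — each sample-weight vector is normalized to sum 1, so
  the statistic is a discrepancy of weighted empirical measures and
  MMD(X, X) = 0 holds exactly; binary subsampling weights become 1/n_active.
  σ is computed on unweighted, feature-unscaled standardized pooled rows
  (exact for ≤ 2000 rows, seeded subsample above). A radicand in
  [−1e−12, 0) is clamped to 0.
- **Corrected t-test** — t = m/√((1/n + n_test/n_train)·s²) with n − 1
  degrees of freedom; under fold scores equicorrelated at
  ρ = n_test/(n_test+n_train) (the overlap structure the correction is
  built for) its rejection rate is nominal, which the tests verify by
  simulation. Benjamini–Hochberg adjustment is delegated to statsmodels.

## Synthetic data: what it emulates and what it does not

`generate_population` draws standard-Gaussian numeric features and uniform
multinomial categoricals; the outcome is logistic in the numeric features
with default coefficients (1.5, 1.0, 0.5, 0, …): some features predictive,
others pure noise. Bias is injected by retaining a seeded 10% of the
positive rows (all negatives kept) — the composition shift then biases
exactly the predictive features while the noise features stay
representative, reproducing the structure that motivates feature
weighting. The evaluation split mirrors the benchmark protocol: 5 folds,
train half biased → `N` (outcome kept), other half → `R` (outcome
structurally withheld by the role-typed container), untouched test fold
`T`.

Not emulated: real covariate dependence structures, nonlinear bias
mechanisms, measurement error, missingness, and ordinal scales. Passing
tests demonstrate the mechanisms (convergence, drop/temperature trade-off,
MMD reduction) under clean Gaussian conditions, not performance on any
particular real survey.

## Problem sizes and fixture choices

The test and acceptance fixtures are scaled to desk-size while keeping
each check's Monte-Carlo noise below its decision margin:

- null-convergence: 200 + 200 rows, 20 seeds, 50-tree domain forest;
- MMD-reduction: populations of 1200 (N ≈ 260 after bias), 20 seeds, the
  linear-SVM variant at t = 0.1 — the injected bias is a location/
  composition shift, which is exactly the linear variant's regime, and its
  fold AUROCs are stable enough that the loop reliably leaves the starting
  block (the forest variant at desk scale frequently stops at iteration
  one with zero drops, leaving nothing to measure);
- temperature trend: 70 + 70 rows, one feature shifted by +2 sd, four
  representative, 20 shared seeds across a 4-point sub-grid
  (0.0025, 0.025, 0.1, 0.5) of the standard 9-point grid, 25-tree forests;
- loop-contract checks: 200 + 200 rows with a +0.8 sd shift, d = 5,
  25-tree forests;
- benchmark harness snapshots: 300–500-row populations, reduced grids, and
  25–100-tree forests.

Defaults in the library itself remain at the protocol values (200-tree
domain forest, 500-tree downstream forest, d = 1 with d = 5 for large
datasets, 10 × 5-fold repetition, the full temperature /
min-weight-fraction / C grids).

## Known limitations

- The loop retrains k classifiers per iteration; cost grows linearly in
  iterations × folds × forest size. For large data, the linear-SVM variant
  or permutation importances are the practical route.
- Tree-Shapley cost is O(trees × foreground × background × leaves); the
  seeded subsampling caps it, at some attribution variance.
- Binary weights mean downstream estimators see a subsample, not a
  continuously reweighted sample; variance-optimal soft weights are out of
  scope.
- AUROC-at-chance is a necessary, not sufficient, condition for
  distributional alignment with a finite classifier family; the weighted
  MMD is reported alongside for that reason.
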