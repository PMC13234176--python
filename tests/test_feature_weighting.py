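import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.tree import DecisionTreeClassifier

from fwmrs import (
    DomainClassifierSpec,
    ImportanceVector,
    estimate_importance,
    softmin_weights,
    train_domain_classifier,
)
from fwmrs._treeshap import forest_interventional_shap
from fwmrs.weighted_learners import auroc

PAPER_TEMPERATURES = [0.001, 0.0025, 0.005, 0.01, 0.025, 0.05, 0.1, 0.25, 0.5]


class TestSoftmin:
    def test_uniform_importance_is_fixed_point(self):
        for t in PAPER_TEMPERATURES:
            w = softmin_weights(np.full(4, 0.25), t)
            np.testing.assert_allclose(np.asarray(w), 0.25, atol=1e-12)

    def test_two_feature_closed_form(self):
        # I = (0.6, 0.4), t = 0.1: weights (1/(1+e^2), e^2/(1+e^2))
        w = np.asarray(softmin_weights(np.array([0.6, 0.4]), 0.1))
        e2 = math.exp(2.0)
        np.testing.assert_allclose(w, [1 / (1 + e2), e2 / (1 + e2)], rtol=1e-12)

    @pytest.mark.parametrize("t", PAPER_TEMPERATURES)
    def test_normalization_over_temperature_grid(self, t, rng):
        imp = rng.dirichlet(np.ones(8))
        assert abs(np.asarray(softmin_weights(imp, t)).sum() - 1.0) < 1e-9

    def test_low_temperature_concentrates_on_argmin(self):
        w = np.asarray(softmin_weights(np.array([0.5, 0.1, 0.4]), 1e-4))
        assert w[1] > 1 - 1e-9
        # ties at the minimum split the weight equally
        w = np.asarray(softmin_weights(np.array([0.5, 0.1, 0.1]), 1e-4))
        np.testing.assert_allclose(w[1:], 0.5, atol=1e-9)

    def test_high_temperature_limit_is_uniform(self, rng):
        imp = rng.dirichlet(np.ones(6))
        w = np.asarray(softmin_weights(imp, 1e6))
        assert np.abs(w - 1 / 6).max() < 1e-6

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            softmin_weights(np.array([0.5, 0.5]), 0.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=10),
           st.floats(1e-3, 10.0), st.floats(-5, 5))
    def test_shift_invariance_and_monotone_reversal(self, imp, t, shift):
        imp = np.asarray(imp)
        w = np.asarray(softmin_weights(imp, t))
        w_shifted = np.asarray(softmin_weights(imp + shift, t))
        np.testing.assert_allclose(w, w_shifted, atol=1e-9)
        # lower importance -> higher weight (strict once the gap is
        # resolvable at this temperature in float arithmetic)
        for i, j in itertools.combinations(range(len(imp)), 2):
            if imp[i] < imp[j]:
                assert w[i] >= w[j]
                if (imp[j] - imp[i]) / t > 1e-9:
                    assert w[i] > w[j]

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.permutations(list(range(5))), st.floats(1e-2, 2.0))
    def test_permutation_equivariance(self, perm, t):
        imp = np.array([0.05, 0.1, 0.2, 0.3, 0.35])
        perm = np.asarray(perm)
        w = np.asarray(softmin_weights(imp, t))
        w_perm = np.asarray(softmin_weights(imp[perm], t))
        np.testing.assert_allclose(w_perm, w[perm], atol=1e-12)


class TestTreeShapley:
    def brute_force(self, tree, x, z, p):
        """Exact interventional Shapley by subset enumeration."""
        cls = list(tree.classes_)

        def f(S):
            v = np.where(np.isin(np.arange(p), list(S)), x, z)
            proba = tree.predict_proba(v.reshape(1, -1))[0]
            return proba[cls.index(1)] if 1 in cls else 0.0

        phi = np.zeros(p)
        for i in range(p):
            others = [j for j in range(p) if j != i]
            for r in range(p):
                for S in itertools.combinations(others, r):
                    w = math.factorial(r) * math.factorial(p - r - 1) / math.factorial(p)
                    phi[i] += w * (f(set(S) | {i}) - f(set(S)))
        return phi

    def test_matches_subset_enumeration(self, rng):
        X = rng.standard_normal((60, 4))
        y = (X[:, 0] + 0.8 * X[:, 1] - 0.3 * X[:, 2] > 0).astype(int)
        tree = DecisionTreeClassifier(max_depth=4, random_state=0).fit(X, y)
        fore, back = X[:6], X[10:25]
        phi = forest_interventional_shap([tree], fore, back)
        for i in range(len(fore)):
            expected = np.mean(
                [self.brute_force(tree, fore[i], z, 4) for z in back], axis=0)
            np.testing.assert_allclose(phi[i], expected, atol=1e-10)

    def test_efficiency_sums_to_prediction_gap(self, rng):
        X = rng.standard_normal((80, 3))
        y = (X[:, 0] > 0).astype(int)
        tree = DecisionTreeClassifier(random_state=0).fit(X, y)
        fore, back = X[:10], X[20:50]
        phi = forest_interventional_shap([tree], fore, back)
        pred = tree.predict_proba(fore)[:, 1]
        base = tree.predict_proba(back)[:, 1].mean()
        np.testing.assert_allclose(phi.sum(axis=1), pred - base, atol=1e-10)


class TestImportance:
    def test_linear_shapley_matches_hand_computation(self, rng):
        X = rng.standard_normal((100, 2))
        X = (X - X.mean(0)) / X.std(0)

        class Stub:
            coef_ = np.array([[2.0, 0.0]])

        imp = estimate_importance(Stub(), X, DomainClassifierSpec(family="linear_svm"),
                                  method="linear_shapley")
        raw = np.abs(np.array([2.0, 0.0]) * (X - X.mean(0))).mean(axis=0)
        np.testing.assert_allclose(np.asarray(imp), raw / raw.sum(), atol=1e-12)
        assert np.asarray(imp)[1] == 0.0

    def test_constant_column_gets_zero_importance(self, rng):
        X = rng.standard_normal((120, 3))
        X[:, 2] = 1.0
        y = (X[:, 0] > 0).astype(int)
        from sklearn.ensemble import RandomForestClassifier

        clf = RandomForestClassifier(n_estimators=20, random_state=0).fit(X, y)
        imp = estimate_importance(clf, X, DomainClassifierSpec(n_trees=20))
        assert np.asarray(imp)[2] == 0.0
        assert abs(np.asarray(imp).sum() - 1.0) < 1e-9

    def test_all_zero_importances_fall_back_to_uniform(self):
        with pytest.warns(UserWarning, match="uniform"):
            iv = ImportanceVector(np.zeros(4))
        np.testing.assert_allclose(np.asarray(iv), 0.25)

    def test_separating_feature_outranks_noise(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            Xn = rng.standard_normal((80, 3))
            Xr = rng.standard_normal((80, 3))
            Xn[:, 0] += 4.0  # feature 0 perfectly separates the sources
            spec = DomainClassifierSpec(n_trees=30, random_seed=seed)
            clf = train_domain_classifier(Xn, Xr, spec)
            imp = np.asarray(estimate_importance(clf, np.vstack([Xn, Xr]), spec))
            hits += imp[0] > max(imp[1], imp[2])
        assert hits >= 19  # >= 95% of runs


class TestDomainClassifier:
    def test_indistinguishable_sources_score_near_chance(self):
        aurocs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            Xn, Xr = rng.standard_normal((150, 5)), rng.standard_normal((150, 5))
            spec = DomainClassifierSpec(n_trees=50, random_seed=seed)
            clf = train_domain_classifier(Xn[:100], Xr[:100], spec)
            X_hold = np.vstack([Xn[100:], Xr[100:]])
            y_hold = np.repeat([0, 1], 50)
            aurocs.append(auroc(clf.predict_proba(X_hold)[:, 1], y_hold))
        assert 0.40 <= np.mean(aurocs) <= 0.60

    def test_shifted_source_is_easily_detected(self):
        rng = np.random.default_rng(0)
        Xn, Xr = rng.standard_normal((200, 5)), rng.standard_normal((200, 5))
        Xr[:, 0] += 3.0
        spec = DomainClassifierSpec(n_trees=50, random_seed=0)
        clf = train_domain_classifier(Xn[:150], Xr[:150], spec)
        X_hold = np.vstack([Xn[150:], Xr[150:]])
        score = auroc(clf.predict_proba(X_hold)[:, 1], np.repeat([0, 1], 50))
        assert score > 0.9

    def test_empty_reference_is_an_error(self, rng):
        with pytest.raises(ValueError):
            train_domain_classifier(rng.standard_normal((5, 2)),
                                    np.empty((0, 2)), DomainClassifierSpec())
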