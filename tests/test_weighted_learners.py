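import numpy as np
import pytest
from sklearn.svm import LinearSVC

from fwmrs import (
    FeatureWeightedLinearSVM,
    SingleClassError,
    WeightedRandomForestClassifier,
    auroc,
)


def pairwise_auroc(scores, labels, weights=None):
    """O(n^2) oracle: weighted share of correctly ordered (pos, neg) pairs."""
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    w = np.ones(len(labels)) if weights is None else np.asarray(weights, float)
    num = den = 0.0
    for i in np.flatnonzero(labels == 1):
        for j in np.flatnonzero(labels == 0):
            wij = w[i] * w[j]
            den += wij
            if scores[i] > scores[j]:
                num += wij
            elif scores[i] == scores[j]:
                num += 0.5 * wij
    return num / den


class TestAuroc:
    def test_perfect_ranking(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auroc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_pairwise_oracle(self, weighted, rng):
        scores = rng.random(50)
        scores[rng.random(50) < 0.2] = 0.5  # inject ties
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        w = rng.random(50) + 0.1 if weighted else None
        assert abs(auroc(scores, labels, w) - pairwise_auroc(scores, labels, w)) < 1e-12

    def test_score_negation_symmetry(self, rng):
        scores, labels = rng.random(40), rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        assert abs(auroc(scores, labels) - (1 - auroc(-scores, labels))) < 1e-12

    def test_single_class_is_signaled(self):
        with pytest.raises(SingleClassError):
            auroc([0.1, 0.9], [1, 1])
        with pytest.raises(SingleClassError):
            auroc([0.1, 0.9], [0, 1], sample_weight=[1.0, 0.0])


class TestWeightedForest:
    def test_zero_weight_feature_never_used(self, rng):
        X = rng.standard_normal((100, 4))
        y = (X[:, 3] > 0).astype(int)  # the excluded column is the informative one
        fw = np.array([1 / 3, 1 / 3, 1 / 3, 0.0])
        clf = WeightedRandomForestClassifier(n_estimators=50, random_state=0)
        clf.fit(X, y, feature_weight=fw)
        assert 3 not in clf.used_features()
        assert all(3 not in feats for feats in clf.feature_subsets_)

    def test_uniform_weights_select_uniformly(self, rng):
        X, y = rng.standard_normal((60, 4)), rng.integers(0, 2, 60)
        clf = WeightedRandomForestClassifier(
            n_estimators=500, max_candidate_features=1, random_state=1)
        clf.fit(X, y)
        counts = np.bincount(
            np.concatenate(clf.feature_subsets_), minlength=4)
        expected, sd = 500 / 4, np.sqrt(500 * 0.25 * 0.75)
        assert np.abs(counts - expected).max() <= 3 * sd

    def test_selection_frequency_proportional_to_weights(self, rng):
        X, y = rng.standard_normal((60, 3)), rng.integers(0, 2, 60)
        clf = WeightedRandomForestClassifier(
            n_estimators=500, max_candidate_features=1, random_state=2)
        clf.fit(X, y, feature_weight=np.array([0.8, 0.1, 0.1]))
        counts = np.bincount(np.concatenate(clf.feature_subsets_), minlength=3)
        assert abs(counts[0] - 500 * 0.8) <= 3 * np.sqrt(500 * 0.8 * 0.2)

    def test_sample_weight_zero_rows_excluded(self, rng):
        X = rng.standard_normal((50, 3))
        y = np.zeros(50, dtype=int)
        y[:25] = 1
        sw = np.ones(50)
        sw[y == 1] = 0.0  # only class 0 survives
        clf = WeightedRandomForestClassifier(n_estimators=5, random_state=0)
        clf.fit(X, y, sample_weight=sw)
        assert clf.classes_.tolist() == [0]

    def test_all_zero_weights_rejected(self, rng):
        X, y = rng.standard_normal((10, 2)), rng.integers(0, 2, 10)
        with pytest.raises(ValueError, match="sample weights"):
            WeightedRandomForestClassifier(n_estimators=2).fit(
                X, y, sample_weight=np.zeros(10))
        with pytest.raises(ValueError, match="feature weights"):
            WeightedRandomForestClassifier(n_estimators=2).fit(
                X, y, feature_weight=np.zeros(2))

    def test_deterministic_given_seed(self, rng):
        X, y = rng.standard_normal((80, 4)), rng.integers(0, 2, 80)
        a = WeightedRandomForestClassifier(n_estimators=20, random_state=5).fit(X, y)
        b = WeightedRandomForestClassifier(n_estimators=20, random_state=5).fit(X, y)
        np.testing.assert_array_equal(a.predict_proba(X), b.predict_proba(X))


class TestFeatureWeightedSVM:
    def test_zero_weight_column_contributes_nothing(self, rng):
        X = rng.standard_normal((100, 3))
        y = (X[:, 0] > 0).astype(int)
        clf = FeatureWeightedLinearSVM(random_state=0)
        clf.fit(X, y, feature_weight=np.array([0.5, 0.5, 0.0]))
        assert clf.coef_[0, 2] == 0.0
        X2 = X.copy()
        X2[:, 2] = 999.0  # arbitrary change in the dead column
        np.testing.assert_allclose(clf.decision_function(X),
                                   clf.decision_function(X2))

    def test_separable_clusters_reach_perfect_training_auroc(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, (30, 2)), rng.normal(3, 0.3, (30, 2))])
        y = np.repeat([0, 1], 30)
        clf = FeatureWeightedLinearSVM(random_state=0)
        clf.fit(X, y, feature_weight=np.array([0.7, 0.3]))
        assert auroc(clf.predict_proba(X)[:, 1], y) == 1.0

    def test_uniform_scaling_preserves_decision_ordering(self, rng):
        X = rng.standard_normal((120, 4))
        y = (X @ np.array([1.0, -0.5, 0.3, 0.0]) + 0.2 * rng.standard_normal(120) > 0)
        p = X.shape[1]
        weighted = FeatureWeightedLinearSVM(C=1.0, random_state=0)
        weighted.fit(X, y.astype(int), feature_weight=np.full(p, 1 / p))
        plain = LinearSVC(C=1.0 / p**2, random_state=0, max_iter=5000).fit(X, y)
        rank_w = np.argsort(weighted.decision_function(X))
        rank_p = np.argsort(plain.decision_function(X))
        assert (rank_w == rank_p).mean() > 0.95

    def test_duplicated_row_equals_doubled_weight(self, rng):
        X = rng.standard_normal((40, 3))
        y = (X[:, 0] + 0.3 * rng.standard_normal(40) > 0).astype(int)
        w = np.ones(40)
        w[7] = 2.0
        doubled = FeatureWeightedLinearSVM(random_state=0).fit(X, y, sample_weight=w)
        X_dup = np.vstack([X, X[7:8]])
        y_dup = np.append(y, y[7])
        duplicated = FeatureWeightedLinearSVM(random_state=0).fit(X_dup, y_dup)

        def objective(clf, X, y, sw):
            margins = 1 - (2 * y - 1) * clf._svm.decision_function(X)
            # liblinear regularizes the intercept as an appended feature
            return (0.5 * (np.sum(clf._svm.coef_ ** 2) + clf._svm.intercept_[0] ** 2)
                    + 1.0 * np.sum(sw * np.maximum(margins, 0)))

        o1 = objective(doubled, X, y, w)
        o2 = objective(duplicated, X, y, w)
        assert abs(o1 - o2) / max(abs(o1), 1e-12) < 1e-3

    def test_single_class_is_an_error(self, rng):
        with pytest.raises(SingleClassError):
            FeatureWeightedLinearSVM().fit(rng.standard_normal((10, 2)),
                                           np.zeros(10, dtype=int))
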