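"""Logistic-regression coupling models: scaling, CV, metrics, diagnostics."""

import numpy as np
import pytest
from oracles import gd_logistic, rank_auc
from sklearn.model_selection import StratifiedKFold

from gcoupler.classify import (
    CouplingClassifier,
    ModelBundle,
    TrainingConfig,
    _apply_minmax,
    _fit_minmax,
    compute_metrics,
    feature_relevance,
    objective,
    randomization_test,
    sigmoid,
    train,
)


def separable_data(rng, n=80, p=6, gap=3.0):
    y = np.arange(n) % 2 == 0
    X = rng.normal(size=(n, p))
    X[y, 0] += gap
    X[y, 1] -= gap
    return X, y


def noisy_data(rng, n=60, p=4):
    y = np.arange(n) % 2 == 0
    X = rng.normal(size=(n, p))
    X[y, 0] += 0.8
    return X, y


class TestScaling:
    def test_midpoint_maps_to_half(self):
        X = np.array([[2.0], [6.0], [4.0]])
        lo, hi = _fit_minmax(X)
        assert _apply_minmax(np.array([[4.0]]), lo, hi)[0, 0] == 0.5

    def test_constant_feature_maps_to_zero(self):
        X = np.full((5, 1), 3.3)
        lo, hi = _fit_minmax(X)
        assert np.all(_apply_minmax(X, lo, hi) == 0.0)

    def test_out_of_range_values_clipped(self):
        X = np.array([[0.0], [10.0]])
        lo, hi = _fit_minmax(X)
        out = _apply_minmax(np.array([[-5.0], [15.0]]), lo, hi)
        assert out.min() == 0.0 and out.max() == 1.0


class TestFit:
    def test_separable_data_reaches_high_cv_auc(self, rng):
        X, y = separable_data(rng)
        clf = CouplingClassifier(n_repeats=3, random_state=1).fit(X, y)
        assert clf.cv_auc_mean_ >= 0.95

    def test_same_seed_identical_model(self, rng):
        X, y = noisy_data(rng)
        a = CouplingClassifier(n_repeats=2, random_state=3).fit(X, y)
        b = CouplingClassifier(n_repeats=2, random_state=3).fit(X, y)
        assert a.C_ == b.C_
        assert np.array_equal(a.coef_, b.coef_)
        assert a.intercept_ == b.intercept_
        assert a.cv_auc_mean_ == b.cv_auc_mean_

    def test_stratified_folds_preserve_class_ratio(self):
        # 10 positives / 40 negatives over 5 folds -> exactly 2 positives each
        y = np.array([1] * 10 + [0] * 40)
        skf = StratifiedKFold(5, shuffle=True, random_state=0)
        for _, test_idx in skf.split(np.zeros((50, 1)), y):
            assert y[test_idx].sum() == 2

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        with pytest.raises(ValueError):
            CouplingClassifier().fit(X, np.ones(20, dtype=bool))

    def test_tiny_minority_class_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.array([True] * 3 + [False] * 17)
        with pytest.raises(ValueError):
            CouplingClassifier(n_folds=5).fit(X, y)

    def test_monotone_regularization_path(self, rng):
        X, y = noisy_data(rng)
        X = _apply_minmax(X, *_fit_minmax(X))
        norms = []
        for C in [1e-3, 1e-2, 1e-1, 1, 10, 100]:
            clf = CouplingClassifier(C_grid=[C], n_repeats=1,
                                     class_weight=None).fit(X, y)
            norms.append(np.linalg.norm(clf.coef_))
        assert all(a <= b + 1e-8 for a, b in zip(norms, norms[1:]))

    def test_label_flip_negates_model(self, rng):
        X, y = noisy_data(rng)
        kwargs = dict(C_grid=[1.0], n_repeats=1, class_weight=None, random_state=0)
        a = CouplingClassifier(**kwargs).fit(X, y)
        b = CouplingClassifier(**kwargs).fit(X, ~y)
        assert np.allclose(a.coef_, -b.coef_, atol=1e-6)
        assert a.intercept_ == pytest.approx(-b.intercept_, abs=1e-6)


class TestObjectiveOracle:
    def test_refit_matches_gradient_descent_objective(self, rng):
        """The fitted cost equals a from-scratch gradient-descent optimum."""
        X, y = noisy_data(rng, n=30, p=3)
        Xs = _apply_minmax(X, *_fit_minmax(X))
        C = 1.0
        clf = CouplingClassifier(C_grid=[C], n_repeats=1,
                                 class_weight=None).fit(Xs, y)
        y_pm = np.where(y, 1.0, -1.0)
        f_impl = objective(clf.coef_, clf.intercept_, Xs, y_pm, C)
        _, _, f_oracle = gd_logistic(Xs, y_pm, C)
        assert f_impl == pytest.approx(f_oracle, abs=1e-6)

    def test_first_order_conditions_hold(self, rng):
        X, y = noisy_data(rng, n=40, p=4)
        Xs = _apply_minmax(X, *_fit_minmax(X))
        C = 2.0
        clf = CouplingClassifier(C_grid=[C], n_repeats=1,
                                 class_weight=None).fit(Xs, y)
        y_pm = np.where(y, 1.0, -1.0)
        w, c = clf.coef_, clf.intercept_
        sig = sigmoid(-y_pm * (Xs @ w + c))
        grad_w = w - C * Xs.T @ (y_pm * sig)
        grad_c = -C * float(np.sum(y_pm * sig))
        assert np.sqrt(grad_w @ grad_w + grad_c**2) <= 1e-6


class TestPredictProba:
    def test_matches_direct_sigmoid_to_1e12(self, rng):
        X, y = noisy_data(rng)
        clf = CouplingClassifier(n_repeats=1).fit(X, y)
        Xq = rng.normal(size=(10, X.shape[1]))
        p = clf.predict_proba(Xq)[:, 1]
        z = clf._scale(Xq) @ clf.coef_ + clf.intercept_
        expected = 1.0 / (1.0 + np.exp(-z))
        assert np.allclose(p, expected, atol=1e-12)
        assert np.all((p > 0) & (p < 1))

    def test_zero_score_gives_half(self):
        bundle = ModelBundle("G", np.zeros(3), 0.0, 1.0,
                             np.zeros(3), np.ones(3), 0.5, 0.0)
        assert bundle.predict_proba(np.array([0.3, 0.7, 0.1]))[0] == 0.5

    def test_length_mismatch_rejected(self, rng):
        X, y = noisy_data(rng)
        clf = CouplingClassifier(n_repeats=1).fit(X, y)
        with pytest.raises(ValueError):
            clf.predict_proba(np.zeros((2, X.shape[1] + 1)))


class TestMetrics:
    def test_perfect_predictions(self):
        m = compute_metrics([0.9, 0.8, 0.1, 0.2], [True, True, False, False])
        assert (m.MCC, m.ACC, m.AUC) == (1.0, 1.0, 1.0)

    def test_hand_confusion_matrix(self):
        # TP=3, FP=1, TN=5, FN=1
        probs = [0.9, 0.9, 0.9, 0.1] + [0.1] * 5 + [0.9]
        labels = [True] * 4 + [False] * 6
        m = compute_metrics(probs, labels)
        assert m.PRE == pytest.approx(0.75)
        assert m.REC == pytest.approx(0.75)
        assert m.SPE == pytest.approx(5 / 6)

    def test_random_probabilities_give_chance_auc(self, rng):
        probs = rng.random(1000)
        labels = rng.random(1000) < 0.5
        m = compute_metrics(probs, labels)
        assert m.AUC == pytest.approx(0.5, abs=0.05)

    def test_auc_equals_pairwise_rank_oracle(self, rng):
        probs = np.round(rng.random(40), 1)  # force ties
        labels = rng.random(40) < 0.5
        m = compute_metrics(probs, labels)
        assert m.AUC == pytest.approx(rank_auc(probs, labels), abs=1e-12)

    def test_single_class_degrades_gracefully(self):
        m = compute_metrics([0.9, 0.2], [True, True])
        assert np.isnan(m.AUC) and np.isnan(m.MCC)
        assert m.ACC == 0.5


class TestRelevanceAndRandomization:
    def test_relevance_is_ranked_permutation(self, rng):
        w = rng.normal(size=6)
        names = [f"f{i}" for i in range(6)]
        ranked = feature_relevance(w, names)
        assert sorted(n for n, _ in ranked) == sorted(names)
        mags = [abs(v) for _, v in ranked]
        assert mags == sorted(mags, reverse=True)

    def test_weights_shrink_with_stronger_regularization(self, rng):
        X, y = separable_data(rng)
        big = CouplingClassifier(C_grid=[10.0], n_repeats=1).fit(X, y)
        small = CouplingClassifier(C_grid=[1e-3], n_repeats=1).fit(X, y)
        assert np.abs(small.coef_).max() < np.abs(big.coef_).max()

    def test_zero_randomizations_empty(self, rng):
        X, y = noisy_data(rng)
        out = randomization_test(X, y, n_randomizations=0)
        assert out.size == 0

    def test_randomized_labels_lose_signal(self, rng):
        X, y = separable_data(rng, n=50)
        config = TrainingConfig(c_grid=(0.1, 1.0, 10.0), n_repeats=1)
        true_auc = CouplingClassifier(
            C_grid=config.c_grid, n_repeats=1, random_state=0
        ).fit(X, y).cv_auc_mean_
        rand = randomization_test(X, y, config, n_randomizations=5, seed=0)
        assert true_auc >= 0.95
        assert rand.mean() < 0.75


def test_bundle_json_roundtrip(tmp_path, rng):
    X, y = noisy_data(rng)
    bundle, clf = train(X, y, TrainingConfig(n_repeats=2), galpha="GNAS",
                        feature_names=[f"f{i}" for i in range(X.shape[1])])
    path = tmp_path / "model.json"
    bundle.to_json(path)
    back = ModelBundle.from_json(path)
    Xq = rng.normal(size=(5, X.shape[1]))
    assert np.allclose(back.predict_proba(Xq), bundle.predict_proba(Xq))
    assert back.C == bundle.C and back.galpha == "GNAS"
    # the bundle reproduces the estimator's probabilities exactly
    assert np.allclose(bundle.predict_proba(Xq), clf.predict_proba(Xq)[:, 1])


def test_sklearn_estimator_interface(rng):
    X, y = noisy_data(rng)
    clf = CouplingClassifier(n_repeats=1)
    assert clf.get_params()["n_repeats"] == 1
    clf.set_params(n_repeats=2).fit(X, y)
    assert clf.predict(X).dtype == np.bool_
    from sklearn.base import clone

    clone(clf)
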