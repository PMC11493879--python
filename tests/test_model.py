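import numpy as np
import pytest

from aosdetect.model import (
    AoSDetector,
    SplitSpec,
    default_family_grids,
    evaluate,
    fit_normalizer,
    grid_search_train,
    mann_whitney_auroc,
    metrics_from_counts,
    smote_oversample,
    stratified_split,
)


class TestStratifiedSplit:
    def test_cohort_arithmetic(self):
        """101 + 48 patients at 75% training: 75 + 36 train, 38 test."""
        y = np.array([1] * 101 + [0] * 48)
        X = np.zeros((149, 2))
        tr, te = stratified_split(X, y, SplitSpec(seed=0))
        assert len(te) == 38
        assert (y[tr] == 1).sum() == 75
        assert (y[tr] == 0).sum() == 36

    def test_tiny_balanced(self):
        y = np.array([0, 0, 1, 1])
        tr, te = stratified_split(np.zeros((4, 1)), y, SplitSpec(seed=3))
        assert len(tr) == 3 and len(te) == 1

    def test_determinism_and_disjointness(self):
        y = np.array([1] * 30 + [0] * 20)
        X = np.zeros((50, 1))
        a = stratified_split(X, y, SplitSpec(seed=7))
        b = stratified_split(X, y, SplitSpec(seed=7))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        assert set(a[0]).isdisjoint(a[1])
        assert len(set(a[0]) | set(a[1])) == 50

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(np.zeros((10, 1)), np.ones(10), SplitSpec())


class TestSmote:
    def _data(self, n_min=36, n_maj=75, d=5, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 1, (n_min, d)), rng.normal(3, 1, (n_maj, d))])
        y = np.array([0] * n_min + [1] * n_maj)
        return X, y

    def test_minority_matched_to_majority(self):
        X, y = self._data()
        Xb, yb = smote_oversample(X, y, k=5, seed=1)
        assert (yb == 0).sum() == 75
        assert (yb == 1).sum() == 75
        # originals retained verbatim
        assert np.array_equal(Xb[:111], X)

    def test_two_point_minority_collinear(self):
        """With two minority points every synthetic sample lies on the
        segment between them."""
        X = np.vstack([[0.0, 0.0], [1.0, 2.0], *np.random.default_rng(0).normal(5, 1, (10, 2))])
        y = np.array([0, 0] + [1] * 10)
        Xb, yb = smote_oversample(X, y, k=1, seed=2)
        synth = Xb[12:]
        for p in synth:
            # p = a + lam*(b-a): cross-product with (b-a) vanishes
            cross = p[0] * 2.0 - p[1] * 1.0
            assert cross == pytest.approx(0.0, abs=1e-12)
            assert -1e-12 <= p[0] <= 1.0 + 1e-12

    def test_synthetic_points_in_parent_box(self):
        X, y = self._data(n_min=10, n_maj=30, d=4, seed=3)
        Xb, yb = smote_oversample(X, y, k=5, seed=4)
        Xmin = X[y == 0]
        for p in Xb[40:]:
            assert np.all(p >= Xmin.min(axis=0) - 1e-12)
            assert np.all(p <= Xmin.max(axis=0) + 1e-12)

    def test_small_minority_reduces_k(self):
        X, y = self._data(n_min=4, n_maj=20, seed=5)
        with pytest.warns(UserWarning, match="reducing k"):
            Xb, yb = smote_oversample(X, y, k=5, seed=6)
        assert (yb == 0).sum() == 20

    def test_determinism(self):
        X, y = self._data()
        a = smote_oversample(X, y, seed=9)[0]
        b = smote_oversample(X, y, seed=9)[0]
        assert np.array_equal(a, b)


class TestNormalizer:
    def test_min_max_mapping(self):
        scaler = fit_normalizer(np.array([[2.0], [4.0], [6.0]]))
        out = scaler.transform(np.array([[2.0], [4.0], [6.0]]))
        assert out.ravel().tolist() == [0.0, 0.5, 1.0]

    def test_test_values_may_exit_unit_interval(self):
        scaler = fit_normalizer(np.array([[2.0], [4.0], [6.0]]))
        assert scaler.transform([[8.0]])[0, 0] == pytest.approx(1.5)

    def test_inverse_round_trip(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 6))
        scaler = fit_normalizer(X)
        back = scaler.inverse_transform(scaler.transform(X))
        assert np.allclose(back, X, atol=1e-12)

    def test_constant_column_to_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            scaler = fit_normalizer(np.array([[1.0, 5.0], [2.0, 5.0]]))
        assert scaler.transform([[1.5, 5.0]])[0, 1] == 0.0


class TestGridSearch:
    def test_table_optimum_reachable(self):
        """The final published hyperparameters (logistic regression, C=10,
        500 iterations, L2, intercept) are a grid point."""
        fams = default_family_grids(0)
        name, proto, grid = fams[0]
        assert name == "logistic-regression"
        assert {"C": 10.0} in grid
        assert proto.max_iter == 500
        assert proto.fit_intercept is True
        # ridge (L2) regularization: no L1 mixing
        assert proto.get_params().get("l1_ratio") in (None, 0.0)

    def test_separable_data_perfect_cv(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.3, (40, 3)), rng.normal(5, 0.3, (40, 3))])
        y = np.array([0] * 40 + [1] * 40)
        res = grid_search_train(X, y, seed=1)
        assert res.mean_auroc == pytest.approx(1.0)

    def test_label_permutation_near_chance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 5))
        y = rng.permutation([0] * 40 + [1] * 40)
        res = grid_search_train(X, y, seed=2)
        # best-of-25-candidates optimism keeps this above 0.5 but well below
        # a real signal
        assert 0.4 <= res.mean_auroc <= 0.75

    def test_cv_report_covers_all_candidates(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        y = np.array([0, 1] * 20)
        res = grid_search_train(X, y, seed=0)
        n_grid = sum(len(g) for _, _, g in default_family_grids(0))
        assert len(res.report) == n_grid


class TestEvaluate:
    def test_published_confusion_matrix_metrics(self):
        """tp 21, fn 5, tn 8, fp 4 reproduce the reported two-decimal
        sensitivity/specificity/accuracy/PPV/NPV."""
        rep = metrics_from_counts(tp=21, fp=4, tn=8, fn=5)
        r = rep.rounded()
        assert r["sensitivity"] == 0.81
        assert r["specificity"] == 0.67
        assert r["accuracy"] == 0.76
        assert r["ppv"] == 0.84
        assert r["npv"] == 0.62

    def test_metrics_consistent_with_counts(self):
        rep = metrics_from_counts(tp=21, fp=4, tn=8, fn=5)
        assert rep.sensitivity == pytest.approx(21 / 26)
        assert rep.specificity == pytest.approx(8 / 12)
        assert rep.accuracy == pytest.approx(29 / 38)
        assert rep.tp + rep.fn == 26
        assert rep.tn + rep.fp == 12

    def test_auroc_tie_convention(self):
        y = np.array([0, 0, 1, 1])
        assert mann_whitney_auroc(y, np.full(4, 0.5)) == pytest.approx(0.5)

    def test_perfect_scores(self):
        y = np.array([0, 0, 1, 1])
        assert mann_whitney_auroc(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            mann_whitney_auroc(np.ones(5), np.random.default_rng(0).random(5))

    def test_mann_whitney_equals_trapezoidal_roc(self):
        """Rank formulation equals trapezoidal ROC integration, including
        under heavy ties."""
        rng = np.random.default_rng(8)
        for _ in range(25):
            y = rng.integers(0, 2, 60)
            if y.min() == y.max():
                continue
            scores = np.round(rng.random(60), 1)  # force ties
            mw = mann_whitney_auroc(y, scores)
            # trapezoidal oracle over the ROC curve
            thr = np.unique(scores)[::-1]
            tpr = [0.0]
            fpr = [0.0]
            for t in thr:
                pred = scores >= t
                tpr.append(np.sum(pred & (y == 1)) / np.sum(y == 1))
                fpr.append(np.sum(pred & (y == 0)) / np.sum(y == 0))
            trap = np.trapezoid(tpr, fpr)
            assert mw == pytest.approx(trap, abs=1e-12)


class TestAoSDetector:
    def test_sklearn_estimator_contract(self):
        det = AoSDetector(smote_k=3, cv_folds=4, random_state=1)
        assert det.get_params()["smote_k"] == 3
        det.set_params(threshold=0.4)
        assert det.threshold == 0.4

    def test_fit_predict_round_trip(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (30, 4)), rng.normal(4, 1, (50, 4))])
        y = np.array([0] * 30 + [1] * 50)
        det = AoSDetector(random_state=0).fit(X, y)
        assert hasattr(det, "classifier_") and hasattr(det, "scaler_")
        rep = det.evaluate(X, y)
        assert rep.auroc > 0.95
        proba = det.predict_proba(X)
        assert proba.shape == (80, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
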