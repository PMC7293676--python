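import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spatlag.models import (
    CombinationModel,
    _best_sse_split,
    combination_weights,
    fit_model_tree,
    fit_pls,
    fit_regression_tree,
    fit_ridge,
    predict_combination,
)


def random_regression(rng, n=60, p=5, noise=1.0):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = 2.0 + X @ beta + noise * rng.normal(size=n)
    return X, y


def ols_fit(X, y):
    A = np.column_stack([np.ones(len(y)), X])
    return np.linalg.lstsq(A, y, rcond=None)[0]


class TestRidge:
    def test_zero_penalty_equals_ols(self, rng):
        X, y = random_regression(rng)
        m = fit_ridge(X, y, penalty=0.0)
        ref = ols_fit(X, y)
        np.testing.assert_allclose(np.r_[m.intercept, m.coef], ref, atol=1e-10)

    def test_closed_form_no_intercept(self):
        # (X'X + I)^-1 X'y with X = (1, 2), y = (1, 2) -> 5/6
        m = fit_ridge(np.array([[1.0], [2.0]]), np.array([1.0, 2.0]),
                      penalty=1.0, fit_intercept=False, standardize=False)
        assert m.coef[0] == pytest.approx(5 / 6, abs=1e-12)

    def test_infinite_penalty_limit(self, rng):
        X, y = random_regression(rng)
        m = fit_ridge(X, y, penalty=1e9)
        assert np.abs(m.coef).max() < 1e-4
        assert m.intercept == pytest.approx(y.mean(), rel=1e-3)

    def test_negative_penalty_rejected(self, rng):
        X, y = random_regression(rng)
        with pytest.raises(ValueError):
            fit_ridge(X, y, penalty=-0.5)

    def test_constant_column_dropped_with_warning(self, rng):
        X, y = random_regression(rng)
        X[:, 2] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            m = fit_ridge(X, y, penalty=1.0)
        assert m.coef[2] == 0.0

    def test_shrinkage_monotone_in_penalty(self, rng):
        X, y = random_regression(rng)
        norms = [
            np.linalg.norm(fit_ridge(X, y, penalty=lam).coef)
            for lam in (0.0, 0.1, 1.0, 10.0, 100.0, 1e4)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_cv_selection_deterministic(self, rng):
        X, y = random_regression(rng, n=80)
        m1 = fit_ridge(X, y, penalty=None, seed=3)
        m2 = fit_ridge(X, y, penalty=None, seed=3)
        assert m1.penalty == m2.penalty
        np.testing.assert_array_equal(m1.coef, m2.coef)


class TestPLS:
    def test_full_rank_equals_ols_predictions(self, rng):
        X, y = random_regression(rng, n=50, p=4)
        m = fit_pls(X, y, n_components=4)
        ref = ols_fit(X, y)
        pred_ols = np.column_stack([np.ones(50), X]) @ ref
        np.testing.assert_allclose(m.predict(X), pred_ols, atol=1e-6)

    def test_univariate_equals_simple_regression(self, rng):
        x = rng.normal(size=(40, 1))
        y = 3.0 - 2.0 * x[:, 0] + 0.5 * rng.normal(size=40)
        m = fit_pls(x, y, n_components=1)
        slope, intercept = np.polyfit(x[:, 0], y, 1)
        assert m.coef[0] == pytest.approx(slope, abs=1e-10)
        assert m.intercept == pytest.approx(intercept, abs=1e-10)

    def test_orthogonal_response_predicts_mean(self):
        # y strictly orthogonal to every centered predictor column
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        y = y - y.mean()
        y = np.array([0.0, 0.0, 0.0, 0.0]) + 5.0  # fully constant: no signal
        with pytest.warns(UserWarning, match="truncated"):
            m = fit_pls(X, y, n_components=2)
        np.testing.assert_allclose(m.predict(X), 5.0)

    def test_training_sse_non_increasing_in_components(self, rng):
        X, y = random_regression(rng, n=60, p=6)
        sses = []
        for a in range(1, 7):
            m = fit_pls(X, y, n_components=a)
            sses.append(float(np.sum((y - m.predict(X)) ** 2)))
        assert all(a >= b - 1e-8 for a, b in zip(sses, sses[1:]))

    def test_excess_components_truncated(self, rng):
        x = rng.normal(size=(30, 1))
        y = x[:, 0] * 2.0
        with pytest.warns(UserWarning, match="truncated"):
            m = fit_pls(x, y, n_components=5)
        assert m.n_components <= 2


class TestRegressionTree:
    def test_two_cluster_split(self):
        X = np.array([[1.0], [2.0], [10.0], [11.0]])
        y = np.array([0.0, 0.0, 10.0, 10.0])
        t = fit_regression_tree(X, y, min_samples_leaf=2)
        assert t.root["threshold"] == 6.0
        assert t.root["left"]["value"] == 0.0
        assert t.root["right"]["value"] == 10.0
        assert float(np.sum((y - t.predict(X)) ** 2)) == 0.0

    def test_constant_response_root_only(self, rng):
        X = rng.normal(size=(30, 3))
        t = fit_regression_tree(X, np.full(30, 4.5))
        assert t.root["leaf"] and t.root["value"] == 4.5

    def test_fully_grown_tree_memorizes(self, rng):
        X = rng.uniform(size=(20, 1))
        y = rng.normal(size=20)
        t = fit_regression_tree(X, y, min_samples_leaf=1, max_depth=64)
        np.testing.assert_allclose(t.predict(X), y, atol=1e-12)

    def test_first_split_matches_brute_force(self, rng):
        for _ in range(10):
            n = int(rng.integers(8, 30))
            X = rng.normal(size=(n, 3))
            y = rng.normal(size=n)
            got = _best_sse_split(X, y, min_leaf=2)
            expected = brute_force_split(X, y, min_leaf=2)
            if expected is None:
                assert got is None
            else:
                assert got[1] == expected[1]
                assert got[2] == pytest.approx(expected[2])
                assert got[0] == pytest.approx(expected[0])

    def test_sse_non_increasing_in_depth(self, rng):
        X = rng.normal(size=(120, 4))
        y = X[:, 0] ** 2 + rng.normal(size=120)
        sses = []
        for depth in range(1, 7):
            t = fit_regression_tree(X, y, min_samples_leaf=5, max_depth=depth)
            sses.append(float(np.sum((y - t.predict(X)) ** 2)))
        assert all(a >= b - 1e-9 for a, b in zip(sses, sses[1:]))

    def test_min_rows_precondition(self, rng):
        with pytest.raises(ValueError):
            fit_regression_tree(rng.normal(size=(5, 2)), rng.normal(size=5),
                                min_samples_leaf=5)


def brute_force_split(X, y, min_leaf):
    """Independent exhaustive split search used as the tree oracle."""
    n, p = X.shape
    base = float(np.sum((y - y.mean()) ** 2))
    best = None
    for j in range(p):
        vals = np.unique(X[:, j])
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = (lo + hi) / 2
            left = X[:, j] <= thr
            nl, nr = left.sum(), (~left).sum()
            if nl < min_leaf or nr < min_leaf:
                continue
            sse = float(np.sum((y[left] - y[left].mean()) ** 2)) + float(
                np.sum((y[~left] - y[~left].mean()) ** 2)
            )
            red = base - sse
            if red <= 1e-12 * max(base, 1.0):
                continue
            # earliest (feature, threshold) wins ties within float noise
            if best is None or red > best[0] + 1e-9 * max(red, 1e-300):
                best = (red, j, thr)
    return best


class TestModelTree:
    def test_piecewise_linear_recovery(self):
        x = np.linspace(-1, 1, 200)[:, None]
        y = np.where(x[:, 0] < 0, 2 * x[:, 0], -3 * x[:, 0])
        t = fit_model_tree(x, y, min_samples_leaf=20, max_depth=5)
        assert t.n_leaves() == 2
        slopes = sorted(
            (t.root["left"]["coef"][0], t.root["right"]["coef"][0])
        )
        assert slopes[0] == pytest.approx(-3.0, abs=1e-3)
        assert slopes[1] == pytest.approx(2.0, abs=1e-3)

    def test_globally_linear_near_zero_error(self):
        x = np.linspace(0, 5, 100)[:, None]
        y = 3 * x[:, 0] + 1
        t = fit_model_tree(x, y, min_samples_leaf=20, max_depth=5)
        assert np.abs(t.predict(x) - y).max() < 1e-6

    def test_constant_response_single_leaf(self, rng):
        X = rng.normal(size=(60, 2))
        t = fit_model_tree(X, np.full(60, 3.3), min_samples_leaf=20)
        assert t.root["leaf"]
        assert t.root["coef"] == [0.0, 0.0]
        assert t.root["intercept"] == 3.3

    def test_leaf_size_must_exceed_feature_count(self, rng):
        X = rng.normal(size=(100, 25))
        with pytest.raises(ValueError, match="features"):
            fit_model_tree(X, rng.normal(size=100), min_samples_leaf=20)


class TestCombination:
    def test_identical_errors_equal_weights(self):
        E = np.tile([1.0, 2.0, 3.0], (4, 1))
        cw = combination_weights(E)
        np.testing.assert_allclose(cw.weights, 0.25)

    def test_known_cv_ratio(self):
        # fold errors with CV exactly 0.1 and 0.3 -> weights 0.75 / 0.25
        d1 = 0.1 / np.sqrt(2)
        d2 = 0.3 / np.sqrt(2)
        E = np.array([[1 - d1, 1 + d1], [1 - d2, 1 + d2]])
        cw = combination_weights(E)
        np.testing.assert_allclose(cw.cv_values, [0.1, 0.3])
        np.testing.assert_allclose(cw.weights, [0.75, 0.25])

    def test_zero_cv_model_takes_all(self):
        E = np.array([[1.0, 1.0, 1.0], [0.5, 1.5, 1.0]])
        cw = combination_weights(E)
        np.testing.assert_allclose(cw.weights, [1.0, 0.0])

    def test_single_model_rejected(self):
        with pytest.raises(ValueError):
            combination_weights(np.array([[1.0, 2.0]]))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            combination_weights(np.zeros((2, 3)))

    @given(
        st.lists(
            st.lists(st.floats(0.01, 10), min_size=3, max_size=3),
            min_size=2,
            max_size=5,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_weights_sum_to_one(self, rows):
        cw = combination_weights(np.asarray(rows))
        assert cw.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert (cw.weights >= 0).all()

    def test_predict_identity_and_midpoint(self, rng):
        X, y = np.ones((5, 2)), np.ones(5)

        class Stub:
            def __init__(self, value):
                self.value = value
                self.n_features = 2
                self.feature_names = None

            def predict(self, X):
                return np.full(len(X), self.value)

        one = combination_weights(np.array([[1.0, 1.0], [2.0, 1.0]]))
        # identity through a weight vector (1, 0)
        np.testing.assert_allclose(
            predict_combination([Stub(10.0), Stub(20.0)], one, X), 10.0
        )
        half = combination_weights(
            np.array([[1 - 0.1, 1 + 0.1], [1 - 0.1, 1 + 0.1]])
        )
        np.testing.assert_allclose(
            predict_combination([Stub(10.0), Stub(20.0)], half, X), 15.0
        )

    def test_misaligned_weights_rejected(self):
        cw = combination_weights(np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(ValueError, match="align"):
            predict_combination([object()], cw, np.ones((2, 1)))

    def test_combination_mse_never_exceeds_worst(self, rng):
        for _ in range(100):
            y = rng.normal(size=30)
            p1 = y + rng.normal(size=30)
            p2 = y + rng.normal(size=30)
            w = rng.uniform()
            comb = w * p1 + (1 - w) * p2
            mse = lambda p: float(np.mean((y - p) ** 2))
            assert mse(comb) <= max(mse(p1), mse(p2)) + 1e-12


class TestSerialization:
    def test_all_models_json_serializable(self, rng):
        X, y = random_regression(rng, n=60, p=3)
        fitted = [
            fit_ridge(X, y, penalty=1.0),
            fit_pls(X, y, n_components=2),
            fit_regression_tree(X, y),
            fit_model_tree(X, y, min_samples_leaf=10),
        ]
        E = np.abs(rng.normal(size=(4, 3))) + 0.1
        cw = combination_weights(E, [m.kind for m in fitted])
        comb = CombinationModel(tuple(fitted), cw)
        blob = json.dumps(comb.to_dict())
        assert "regression_tree" in blob

    def test_feature_name_mismatch_rejected(self, rng):
        import pandas as pd

        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["u", "v"])
        m = fit_ridge(X, rng.normal(size=30), penalty=1.0)
        with pytest.raises(ValueError, match="feature names"):
            m.predict(X.rename(columns={"u": "w"}))
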