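"""Regressors against closed-form oracles; metrics; tuning; model selection."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mflogp.models import (
    ExperimentCell,
    MetricsReport,
    ModelSpec,
    default_spec,
    evaluate,
    fit_from_spec,
    fit_gbr,
    fit_knn,
    fit_lasso,
    fit_mlr,
    fit_random_forest,
    fit_ridge,
    load_model,
    model_header,
    predict,
    save_model,
    select_final,
    tune,
)


@pytest.fixture
def toy_linear(rng):
    X = rng.normal(size=(60, 4))
    beta = np.array([1.5, -2.0, 0.0, 0.7])
    y = X @ beta + 0.25
    return X, y, beta, 0.25


class TestMLR:
    def test_recovers_exact_coefficients(self, toy_linear):
        X, y, beta, intercept = toy_linear
        model = fit_mlr(X, y)
        # independent oracle: normal-equations solve
        design = np.column_stack([np.ones(len(y)), X])
        oracle = np.linalg.solve(design.T @ design, design.T @ y)
        np.testing.assert_allclose(model.params.coefficients, beta, atol=1e-8)
        np.testing.assert_allclose(model.params.intercept, intercept, atol=1e-8)
        np.testing.assert_allclose(model.params.coefficients, oracle[1:], atol=1e-10)

    def test_constant_response(self, rng):
        X = rng.normal(size=(20, 3))
        model = fit_mlr(X, np.full(20, 3.5))
        np.testing.assert_allclose(model.params.coefficients, 0.0, atol=1e-10)
        assert model.params.intercept == pytest.approx(3.5)

    def test_single_column_exact_line(self):
        model = fit_mlr(np.array([[1.0], [2.0], [3.0]]), np.array([2.0, 4.0, 6.0]))
        assert model.params.coefficients[0] == pytest.approx(2.0)
        assert model.params.intercept == pytest.approx(0.0, abs=1e-10)

    def test_rank_deficient_warns_minimum_norm(self, rng):
        x = rng.normal(size=30)
        X = np.column_stack([x, 2 * x])  # collinear
        with pytest.warns(UserWarning, match="minimum-norm"):
            model = fit_mlr(X, 3 * x)
        np.testing.assert_allclose(predict(model, X), 3 * x, atol=1e-8)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            fit_mlr(np.empty((0, 3)), np.empty(0))

    def test_coefficient_error_shrinks_with_n(self):
        rng = np.random.default_rng(0)
        beta = np.array([1.0, -1.0])
        errs = []
        for n in (100, 1000, 10000):
            X = rng.normal(size=(n, 2))
            y = X @ beta + rng.normal(0, 1.0, n)
            model = fit_mlr(X, y)
            errs.append(np.linalg.norm(model.params.coefficients - beta))
        assert errs[0] > errs[1] > errs[2]


class TestRidge:
    def test_zero_penalty_matches_mlr(self, toy_linear):
        X, y, *_ = toy_linear
        np.testing.assert_allclose(
            fit_ridge(X, y, 0.0).params.coefficients,
            fit_mlr(X, y).params.coefficients,
            atol=1e-8,
        )

    def test_huge_penalty_collapses_to_intercept(self, toy_linear):
        X, y, *_ = toy_linear
        model = fit_ridge(X, y, 1e12)
        np.testing.assert_allclose(model.params.coefficients, 0.0, atol=1e-6)
        assert model.params.intercept == pytest.approx(np.mean(y), abs=1e-6)

    def test_one_dimensional_closed_form(self):
        # centered toy: beta = sum(xy) / (sum(x^2) + penalty) = 2/3
        X = np.array([[-1.0], [0.0], [1.0]])
        y = np.array([-1.0, 0.0, 1.0])
        model = fit_ridge(X, y, 1.0)
        assert model.params.coefficients[0] == pytest.approx(2.0 / 3.0, abs=1e-10)

    def test_negative_penalty_raises(self, toy_linear):
        X, y, *_ = toy_linear
        with pytest.raises(ValueError):
            fit_ridge(X, y, -1.0)

    def test_coefficient_norm_nonincreasing_in_penalty(self, toy_linear):
        X, y, *_ = toy_linear
        norms = [
            np.linalg.norm(fit_ridge(X, y, lam).params.coefficients)
            for lam in (0.0, 0.1, 1.0, 10.0, 100.0)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))


def _soft_threshold(z, t):
    return np.sign(z) * max(abs(z) - t, 0.0)


class TestLasso:
    def test_large_penalty_zeroes_everything(self, toy_linear):
        X, y, *_ = toy_linear
        model = fit_lasso(X, y, 1e9)
        np.testing.assert_array_equal(model.params.coefficients, 0.0)
        assert model.params.intercept == pytest.approx(np.mean(y))

    def test_zero_penalty_matches_mlr(self, toy_linear):
        X, y, *_ = toy_linear
        np.testing.assert_allclose(
            fit_lasso(X, y, 0.0).params.coefficients,
            fit_mlr(X, y).params.coefficients,
            atol=1e-6,
        )

    def test_one_dimensional_soft_threshold(self):
        # 1-D coordinate-descent closed form on centered data:
        # beta = S(sum(xy), penalty/2) / sum(x^2)
        X = np.array([[-2.0], [-1.0], [0.0], [1.0], [2.0]])
        y = np.array([-2.1, -0.9, 0.1, 1.1, 1.8])
        for lam in (1.0, 3.0, 8.0):
            expected = _soft_threshold(float(X[:, 0] @ y), lam / 2.0) / float(X[:, 0] @ X[:, 0])
            model = fit_lasso(X, y, lam)
            assert model.params.coefficients[0] == pytest.approx(expected, abs=1e-6)

    def test_nonzero_count_nonincreasing_in_penalty(self, toy_linear):
        X, y, *_ = toy_linear
        nnz = [
            int(np.sum(fit_lasso(X, y, lam).params.coefficients != 0))
            for lam in (0.01, 1.0, 10.0, 100.0, 1e4)
        ]
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_negative_penalty_raises(self, toy_linear):
        X, y, *_ = toy_linear
        with pytest.raises(ValueError):
            fit_lasso(X, y, -0.5)


class TestForest:
    def test_single_full_tree_memorizes_unique_rows(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        spec = ModelSpec(kind="rfr", n_estimators=1, max_depth=None, bootstrap=False)
        model = fit_random_forest(X, y, spec)
        assert evaluate(y, predict(model, X)).rmse == pytest.approx(0.0, abs=1e-12)

    def test_predictions_bounded_by_training_range(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        model = fit_random_forest(X, y, seed=1)
        preds = predict(model, rng.normal(size=(100, 3)) * 5)
        assert preds.min() >= y.min() - 1e-12 and preds.max() <= y.max() + 1e-12

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        a = predict(fit_random_forest(X, y, seed=7), X)
        b = predict(fit_random_forest(X, y, seed=7), X)
        np.testing.assert_array_equal(a, b)

    def test_no_trees_raises(self, rng):
        with pytest.raises(ValueError):
            fit_random_forest(np.ones((5, 1)), np.ones(5), ModelSpec(kind="rfr", n_estimators=0))


class TestGBR:
    def test_training_rss_nonincreasing_in_stages(self, rng):
        X = rng.normal(size=(80, 3))
        y = X[:, 0] - 0.5 * X[:, 1] + rng.normal(0, 0.3, 80)
        rss = []
        for stages in (1, 5, 10, 25, 50):
            spec = ModelSpec(kind="gbr", n_estimators=stages, max_depth=2, learning_rate=0.1, seed=0)
            model = fit_gbr(X, y, spec)
            rss.append(np.sum((y - predict(model, X)) ** 2))
        assert all(a >= b - 1e-9 for a, b in zip(rss, rss[1:]))

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(40, 2))
        y = rng.normal(size=40)
        a = predict(fit_gbr(X, y, seed=3), X)
        b = predict(fit_gbr(X, y, seed=3), X)
        np.testing.assert_array_equal(a, b)

    def test_invalid_spec_raises(self, rng):
        with pytest.raises(ValueError):
            fit_gbr(np.ones((5, 1)), np.ones(5), ModelSpec(kind="gbr", n_estimators=0))
        with pytest.raises(ValueError):
            fit_gbr(np.ones((5, 1)), np.ones(5), ModelSpec(kind="gbr", learning_rate=0.0))


class TestKNN:
    def test_exact_match_with_k1(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        model = fit_knn(X, y, 1)
        np.testing.assert_allclose(predict(model, X), y)

    def test_k_equals_n_predicts_global_mean(self, rng):
        X = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        model = fit_knn(X, y, 15)
        np.testing.assert_allclose(predict(model, np.zeros((3, 2))), np.mean(y))

    def test_tie_at_kth_distance_breaks_to_lowest_index(self):
        # distances from the origin query: 1, 2, 2 -> K=2 takes index 0 then 1
        X = np.array([[1.0, 0.0], [2.0, 0.0], [0.0, 2.0]])
        y = np.array([0.0, 3.0, 5.0])
        model = fit_knn(X, y, 2)
        assert predict(model, np.zeros((1, 2)))[0] == pytest.approx(1.5)

    def test_matches_exhaustive_sort_oracle(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        queries = rng.normal(size=(10, 3))
        k = 5
        model = fit_knn(X, y, k)
        preds = predict(model, queries)
        for q, p in zip(queries, preds):
            dists = np.linalg.norm(X - q, axis=1)
            order = sorted(range(len(X)), key=lambda i: (dists[i], i))
            assert p == pytest.approx(np.mean(y[order[:k]]))

    def test_k_out_of_range_raises(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            fit_knn(X, np.ones(5), 6)
        with pytest.raises(ValueError):
            fit_knn(X, np.ones(5), 0)


class TestPredictDispatch:
    def test_constant_linear_model(self):
        model = fit_mlr(np.zeros((5, 2)) + np.eye(5, 2), np.full(5, 2.0))
        np.testing.assert_allclose(predict(model, np.random.default_rng(0).normal(size=(4, 2))), 2.0, atol=1e-8)

    def test_width_mismatch_names_expected(self, rng):
        X = rng.normal(size=(20, 10))
        model = fit_mlr(X, rng.normal(size=20))
        with pytest.raises(ValueError, match="10"):
            predict(model, rng.normal(size=(3, 21)))


class TestEvaluate:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        report = evaluate(y, y)
        assert (report.rmse, report.mae, report.r2) == (0.0, 0.0, 1.0)

    def test_mean_prediction_gives_r2_zero_exactly(self, rng):
        y = rng.normal(size=30)
        report = evaluate(y, np.full(30, np.mean(y)))
        assert report.r2 == 0.0

    def test_hand_arithmetic(self):
        report = evaluate([0.0, 1.0, 2.0], [0.0, 0.0, 0.0])
        assert report.rmse == pytest.approx(np.sqrt(5.0 / 3.0))
        assert report.mae == pytest.approx(1.0)
        assert report.r2 == pytest.approx(-1.5)

    def test_errors(self):
        with pytest.raises(ValueError):
            evaluate([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            evaluate([1.0], [1.0])

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_rmse_dominates_mae(self, seed):
        r = np.random.default_rng(seed)
        y, yhat = r.normal(size=25), r.normal(size=25)
        report = evaluate(y, yhat)
        assert report.rmse >= report.mae - 1e-12
        assert report.r2 <= 1.0


class TestTune:
    def test_single_point_grid_returned(self, toy_linear):
        X, y, *_ = toy_linear
        spec = tune("ridge", {"penalty": [0.5]}, X, y, seed=0)
        assert spec.penalty == 0.5

    def test_clean_linear_data_prefers_no_penalty(self, toy_linear):
        X, y, *_ = toy_linear
        spec = tune("ridge", {"penalty": [0.0, 1e12]}, X, y, seed=0)
        assert spec.penalty == 0.0

    def test_knn_selection_matches_brute_force_cv_oracle(self, rng):
        X = np.linspace(0, 10, 64)[:, None]
        y = np.sin(X[:, 0]) + rng.normal(0, 0.2, 64)
        grid = {"n_neighbors": [1, 3, 8, 56]}  # 56 = largest K feasible per fold
        spec = tune("knnr", grid, X, y, folds=8, seed=4)
        # oracle: recompute every fold score exhaustively
        from mflogp.models import _cv_folds

        folds = _cv_folds(64, 8, 4)
        scores = {}
        for k in grid["n_neighbors"]:
            fold_scores = []
            for val in folds:
                tr = np.setdiff1d(np.arange(64), val)
                model = fit_knn(X[tr], y[tr], k)
                fold_scores.append(evaluate(y[val], predict(model, X[val])).rmse)
            scores[k] = np.mean(fold_scores)
        assert spec.n_neighbors == min(grid["n_neighbors"], key=lambda k: scores[k])

    def test_too_few_records_raises(self, rng):
        with pytest.raises(ValueError):
            tune("ridge", {"penalty": [1.0]}, rng.normal(size=(5, 2)), np.ones(5), folds=8)


def _cell(kind, rmse, std, extra=False, cv=False, tuned=False):
    m = MetricsReport(rmse, rmse, 0.5)
    s = MetricsReport(std, std, 0.0)
    return ExperimentCell(
        kind=kind,
        extra_features=extra,
        cross_validation=cv,
        tuned_hyperparameters=tuned,
        repeats=10,
        train_mean=m,
        train_std=s,
        valid_mean=m,
        valid_std=s,
        spec=default_spec(kind, extended=extra),
    )


class TestSelectFinal:
    def test_single_cell_returned(self):
        cell = _cell("rfr", 0.8, 0.02)
        assert select_final([cell]) == cell.spec

    def test_clear_separation_lower_wins(self):
        cells = [_cell("mlr", 1.2, 0.01), _cell("rfr", 0.8, 0.01)]
        assert select_final(cells).kind == "rfr"

    def test_within_error_prefers_fewer_features(self):
        base = _cell("rfr", 0.80, 0.02, extra=False)
        extended = _cell("rfr", 0.78, 0.02, extra=True)
        spec = select_final([base, extended])
        assert spec.extended_features is False

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            select_final([])


class TestSerialization:
    def test_round_trip_preserves_predictions(self, tmp_path, rng):
        X = rng.normal(size=(30, 10))
        y = rng.normal(size=30)
        model = fit_from_spec(default_spec("rfr", seed=5), X, y)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(predict(loaded, X), predict(model, X))
        header = model_header(path)
        assert header["n_features"] == 10
        assert header["spec"]["kind"] == "rfr"
        assert "weight_table" in header
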