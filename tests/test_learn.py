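"""MLR fitting, evaluation protocols, and descriptor selection."""

import numpy as np
import pandas as pd
import pytest

from invqspr import (
    EvalProtocol,
    StrategyConfig,
    evaluate,
    fit_mlr,
    fsp_select,
    lasso_select,
    r_squared,
    run_strategy,
)
from invqspr.datagen import planted_regression
from invqspr.learn import STRATEGIES


@pytest.fixture(scope="module")
def linear_data():
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.standard_normal((40, 3)), columns=["a", "b", "c"])
    y = 2.0 + 1.5 * X["a"] - 0.5 * X["c"]
    return X, y.to_numpy()


class TestFitMlr:
    def test_exact_linear_data_recovered(self, linear_data):
        X, y = linear_data
        model = fit_mlr(X, y)
        assert model.intercept == pytest.approx(2.0, abs=1e-9)
        assert model.weights["a"] == pytest.approx(1.5, abs=1e-9)
        assert model.weights["b"] == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(model.predict(X), y)

    def test_constant_column_predicts_mean(self):
        X = pd.DataFrame({"const": np.ones(10)})
        y = np.arange(10.0)
        model = fit_mlr(X, y)
        assert np.allclose(model.predict(X), y.mean())

    def test_matches_pseudoinverse_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 5))
        y = rng.standard_normal(30)
        model = fit_mlr(X, y)
        A = np.column_stack([X, np.ones(30)])
        beta = np.linalg.pinv(A) @ y
        got = np.array([model.weights[f"x{j}"] for j in range(5)] + [model.intercept])
        assert np.allclose(got, beta, atol=1e-8)

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            fit_mlr(pd.DataFrame(), np.array([]))


class TestRSquared:
    def test_perfect_and_mean_predictors(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert r_squared(y, y) == 1.0
        assert r_squared(y, np.full(4, y.mean())) == 0.0

    def test_can_be_hugely_negative(self):
        y = np.array([0.0, 1.0])
        assert r_squared(y, np.array([1e6, -1e6])) < -1e10

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            r_squared(np.ones(5), np.ones(5))


class TestEvaluate:
    def test_perfect_linear_data_scores_one(self, linear_data):
        X, y = linear_data
        for proto in (EvalProtocol("LOOV"), EvalProtocol("KFOLD", 5, 10, seed=1)):
            assert evaluate(X, y, proto).score == pytest.approx(1.0, abs=1e-9)

    def test_loov_is_seed_independent(self, linear_data):
        X, y = linear_data
        y = y + np.random.default_rng(2).normal(0, 0.5, len(y))
        s1 = evaluate(X, y, EvalProtocol("LOOV", seed=1)).score
        s2 = evaluate(X, y, EvalProtocol("LOOV", seed=99)).score
        assert s1 == s2

    def test_kfold_seed_changes_folds_but_is_reproducible(self, linear_data):
        X, y = linear_data
        y = y + np.random.default_rng(2).normal(0, 1.0, len(y))
        r1 = evaluate(X, y, EvalProtocol("KFOLD", 5, 2, seed=1))
        r1b = evaluate(X, y, EvalProtocol("KFOLD", 5, 2, seed=1))
        r2 = evaluate(X, y, EvalProtocol("KFOLD", 5, 2, seed=2))
        assert r1.fold_scores == r1b.fold_scores
        assert r1.fold_scores != r2.fold_scores

    def test_kfold_larger_than_sample_rejected(self, linear_data):
        X, y = linear_data
        with pytest.raises(ValueError, match="exceeds"):
            evaluate(X.iloc[:4], y[:4], EvalProtocol("KFOLD", 5, 1))

    def test_noise_convergence(self):
        """Median k-fold R^2 approaches 1 as the noise level shrinks."""
        scores = []
        for sigma in (1.0, 0.1, 0.01):
            X, y = planted_regression(120, 4, {0: 2.0, 2: -1.0}, sigma, seed=8)
            scores.append(evaluate(X, y, EvalProtocol("KFOLD", 5, 2, seed=0)).score)
        assert scores[0] < scores[1] < scores[2]
        assert scores[2] > 0.999


class TestFspSelect:
    def test_planted_column_found_first(self):
        X, y = planted_regression(100, 51, {7: 3.0}, 0.1, seed=3)
        res = fsp_select(X, y, 3, EvalProtocol("KFOLD", 5, 1, seed=0))
        assert res.names[0] == "x7"

    def test_max_k_one_equals_exhaustive_best_column(self):
        X, y = planted_regression(60, 12, {4: 1.0, 9: 0.5}, 0.3, seed=6)
        proto = EvalProtocol("KFOLD", 4, 1, seed=5)
        res = fsp_select(X, y, 1, proto)
        oracle = max(X.columns, key=lambda c: evaluate(X[[c]], y, proto).score)
        assert res.names == [oracle]

    def test_trajectory_matches_reevaluation(self):
        X, y = planted_regression(80, 10, {1: 2.0, 5: -1.0}, 0.2, seed=9)
        proto = EvalProtocol("KFOLD", 5, 1, seed=2)
        res = fsp_select(X, y, 3, proto, tol=-np.inf)
        for i, score in enumerate(res.trajectory):
            assert score == pytest.approx(
                evaluate(X[res.names[: i + 1]], y, proto).score
            )

    def test_training_r2_never_decreases_with_more_columns(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.standard_normal((50, 8)),
                         columns=[f"x{j}" for j in range(8)])
        y = rng.standard_normal(50)
        prev = -np.inf
        for k in range(1, 9):
            model = fit_mlr(X.iloc[:, :k], y)
            score = r_squared(y, model.predict(X.iloc[:, :k]))
            assert score >= prev - 1e-12
            prev = score

    def test_max_k_too_large_rejected(self):
        X, y = planted_regression(30, 4, {0: 1.0}, 0.1, seed=1)
        with pytest.raises(ValueError):
            fsp_select(X, y, 5)


class TestLassoSelect:
    def test_zero_penalty_keeps_all_informative_columns(self):
        X, y = planted_regression(60, 5, {0: 1.0, 1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0}, 0.0, seed=2)
        assert len(lasso_select(X, y, lam=0.0).names) == 5

    def test_huge_penalty_empties_selection(self):
        X, y = planted_regression(60, 5, {0: 1.0}, 0.1, seed=2)
        assert lasso_select(X, y, lam=1e6).names == []

    def test_sparse_support_recovered_at_moderate_penalty(self):
        X, y = planted_regression(150, 30, {3: 2.0, 17: -1.5}, 0.1, seed=12)
        names = lasso_select(X, y, lam=0.1).names
        assert {"x3", "x17"} <= set(names)
        assert len(names) <= 8


class TestRunStrategy:
    def test_all_strategies_score_one_on_noiseless_data(self):
        X, y = planted_regression(60, 6, {0: 1.0, 3: -2.0}, 0.0, seed=7)
        for name in STRATEGIES:
            _, report, _ = run_strategy(name, X, y, StrategyConfig(max_k=4, seed=0))
            # LASSO's shrinkage bias keeps LLR-LLR marginally below 1
            tol = 1e-3 if name == "LLR-LLR" else 1e-9
            assert report.score == pytest.approx(1.0, abs=tol), name

    def test_fsp_beats_plain_mlr_loo_on_planted_sparse_data(self):
        X, y = planted_regression(60, 55, {2: 2.0, 9: -1.0, 30: 1.0}, 0.3, seed=10)
        cfg = StrategyConfig(max_k=5, seed=0)
        _, loo_report, _ = run_strategy("MLR-LOO", X, y, cfg)
        _, fsp_report, _ = run_strategy("FSP-MLR-LOO", X, y, cfg)
        assert fsp_report.score > loo_report.score

    def test_tiny_dataset_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            run_strategy("MLR", X, np.array([1.0, 2.0]))

    def test_unknown_strategy_rejected(self, linear_data):
        X, y = linear_data
        with pytest.raises(ValueError, match="unknown strategy"):
            run_strategy("GBM", X, y)

    def test_loov_restricted_to_small_datasets(self):
        X, y = planted_regression(160, 3, {0: 1.0}, 0.1, seed=0)
        with pytest.raises(ValueError, match="LOOV"):
            run_strategy("MLR-LOO", X, y)
        cfg = StrategyConfig(allow_large_loov=True)
        model, report, _ = run_strategy("MLR-LOO", X, y, cfg)
        assert report.score > 0.9
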