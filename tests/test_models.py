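import math

import numpy as np
import pytest

from sctfa.models import (
    DEFAULT_LAMBDA_GRID,
    DEFAULT_STL_ALPHA_GRID,
    cross_validate_tree,
    evaluate_per_cell,
    fit_omtl,
    fit_stl,
    fit_tree_guided,
    lambda_max_upper_bound,
    omtl_objective,
    predict,
    prox_tree_norm,
    tree_objective,
    FitResult,
)
from sctfa.preprocess import Standardizer
from sctfa.trees import TaskTree, build_star_tree

from conftest import prox_oracle, random_binary_tree, solve_group_objective_oracle


def naive_tree_objective(X, Y, B, tree, lam):
    """Term-by-term double-loop evaluator, independent of the vectorized path."""
    total = 0.0
    for i in range(Y.shape[1]):
        r = Y[:, i] - X @ B[:, i]
        total += float(r @ r)
    for j in range(B.shape[0]):
        for v in range(tree.n_nodes):
            w = tree.weights[v]
            total += lam * math.sqrt(sum((w * B[j, i]) ** 2 for i in tree.groups[v]))
    return total


@pytest.fixture
def small_instance(rng):
    n, p, k = 30, 6, 4
    X = rng.standard_normal((n, p))
    Y = rng.standard_normal((n, k))
    tree = TaskTree([4, 4, 5, 5, 6, 6, None], [f"c{i}" for i in range(k)])
    return X, Y, tree


class TestTreeObjective:
    def test_zero_coefficients(self, small_instance):
        X, Y, tree = small_instance
        assert tree_objective(X, Y, np.zeros((6, 4)), tree, 0.7) == pytest.approx(
            float((Y**2).sum())
        )

    def test_lambda_zero_is_rss(self, small_instance, rng):
        X, Y, tree = small_instance
        B = rng.standard_normal((6, 4))
        assert tree_objective(X, Y, B, tree, 0.0) == pytest.approx(
            float(((Y - X @ B) ** 2).sum())
        )

    def test_matches_naive_evaluator(self, small_instance, rng):
        X, Y, tree = small_instance
        B = rng.standard_normal((6, 4))
        assert tree_objective(X, Y, B, tree, 0.33) == pytest.approx(
            naive_tree_objective(X, Y, B, tree, 0.33), rel=1e-12
        )

    def test_dimension_mismatch(self, small_instance):
        X, Y, tree = small_instance
        with pytest.raises(ValueError):
            tree_objective(X, Y, np.zeros((5, 4)), tree, 0.1)

    def test_unhalved_weight_inside_norm(self, small_instance):
        # the printed penalty is ||w_v * beta||_2 = w_v * ||beta||_2
        X, Y, tree = small_instance
        B = np.zeros((6, 4))
        B[0, :] = 1.0
        expected = float(((Y - X @ B) ** 2).sum())
        for v in range(tree.n_nodes):
            expected += 1.0 * tree.weights[v] * np.sqrt(len(tree.groups[v]))
        assert tree_objective(X, Y, B, tree, 1.0) == pytest.approx(expected, rel=1e-12)


class TestProxOperator:
    def test_matches_projection_oracle_on_random_rows(self, rng):
        for _ in range(10):
            tree = random_binary_tree(int(rng.integers(2, 7)), rng)
            groups = tree.penalty_groups()
            v = rng.standard_normal(tree.k) * 2
            tau = float(rng.uniform(0.05, 1.0))
            ours = prox_tree_norm(v[None, :], groups, tau)[0]
            oracle = prox_oracle(v, groups, tau)
            assert np.allclose(ours, oracle, atol=5e-6)

    def test_large_tau_zeroes_everything(self, rng):
        tree = random_binary_tree(4, rng)
        v = rng.standard_normal((3, 4))
        assert np.all(prox_tree_norm(v, tree.penalty_groups(), 100.0) == 0)


class TestFitTreeGuided:
    def test_lambda_zero_least_squares(self, small_instance):
        X, Y, tree = small_instance
        fit = fit_tree_guided(X, Y, tree, 0.0)
        expected = np.linalg.lstsq(X, Y, rcond=None)[0]
        assert np.allclose(fit.B, expected, atol=1e-6)

    def test_lambda_max_gives_zero(self, small_instance):
        X, Y, tree = small_instance
        lam = lambda_max_upper_bound(X, Y, tree)
        fit = fit_tree_guided(X, Y, tree, lam * 1.0001, max_iter=2000, tol=1e-12)
        assert np.all(fit.B == 0)

    def test_matches_convex_oracle(self, rng):
        for seed in range(5):
            local = np.random.default_rng(seed)
            X = local.standard_normal((30, 6))
            Y = local.standard_normal((30, 4))
            tree = random_binary_tree(4, local)
            lam = 0.2 * lambda_max_upper_bound(X, Y, tree)
            fit = fit_tree_guided(X, Y, tree, lam, max_iter=20000, tol=1e-14)
            ours = tree_objective(X, Y, fit.B, tree, lam)
            B_oracle = solve_group_objective_oracle(X, Y, tree.penalty_groups(), lam)
            theirs = tree_objective(X, Y, B_oracle, tree, lam)
            assert abs(ours - theirs) / theirs <= 1e-4

    def test_objective_history_nonincreasing(self, small_instance):
        X, Y, tree = small_instance
        fit = fit_tree_guided(X, Y, tree, 0.5)
        h = np.asarray(fit.objective_history)
        assert np.all(np.diff(h) <= 1e-12 * np.maximum(1.0, np.abs(h[:-1])))

    def test_negative_lambda_rejected(self, small_instance):
        X, Y, tree = small_instance
        with pytest.raises(ValueError):
            fit_tree_guided(X, Y, tree, -0.1)

    def test_task_count_mismatch(self, small_instance):
        X, Y, tree = small_instance
        with pytest.raises(ValueError):
            fit_tree_guided(X, Y[:, :3], tree, 0.1)

    def test_objective_nondecreasing_in_lambda(self, small_instance):
        X, Y, tree = small_instance
        values = []
        for lam in np.linspace(0, 2, 9):
            fit = fit_tree_guided(X, Y, tree, float(lam), max_iter=5000, tol=1e-12)
            values.append(tree_objective(X, Y, fit.B, tree, float(lam)))
        assert all(b >= a - 1e-8 for a, b in zip(values, values[1:]))


class TestStarTreePenalty:
    def test_equals_sparse_group_lasso_form(self, rng):
        # star-tree penalty per row: w_root * ||row||_2 + sum_i w_i |row_i|
        tree = build_star_tree([f"c{i}" for i in range(5)])
        X = rng.standard_normal((20, 3))
        Y = rng.standard_normal((20, 5))
        B = rng.standard_normal((3, 5))
        lam = 0.4
        direct = float(((Y - X @ B) ** 2).sum())
        for j in range(3):
            direct += lam * (
                tree.weights[tree.root] * np.linalg.norm(B[j])
                + sum(np.abs(B[j, i]) for i in range(5))
            )
        assert tree_objective(X, Y, B, tree, lam) == pytest.approx(direct, rel=1e-12)

    def test_fit_matches_sparse_group_lasso_oracle(self, rng):
        tree = build_star_tree([f"c{i}" for i in range(4)])
        X = rng.standard_normal((25, 5))
        Y = rng.standard_normal((25, 4))
        lam = 0.15 * lambda_max_upper_bound(X, Y, tree)
        fit = fit_tree_guided(X, Y, tree, lam, max_iter=20000, tol=1e-14)
        sgl_groups = [(np.array([i]), 1.0) for i in range(4)] + [(np.arange(4), 2.0)]
        B_oracle = solve_group_objective_oracle(X, Y, sgl_groups, lam)
        ours = tree_objective(X, Y, fit.B, tree, lam)
        theirs = tree_objective(X, Y, B_oracle, tree, lam)
        assert abs(ours - theirs) / theirs <= 1e-4


class TestFitOmtl:
    def test_huge_penalty_zeroes(self, small_instance):
        X, Y, _ = small_instance
        assert np.all(fit_omtl(X, Y, 1e8).B == 0)

    def test_single_task_reduces_to_lasso(self, rng):
        X = rng.standard_normal((40, 5))
        y = X @ np.array([1.0, -2.0, 0.0, 0.0, 0.5]) + 0.05 * rng.standard_normal(40)
        alpha = 3.0
        fit = fit_omtl(X, y[:, None], alpha, max_iter=20000, tol=1e-14)
        # lasso oracle via sklearn (objective 1/(2n)||.||^2 + a||.||_1 maps to ours)
        from sklearn.linear_model import Lasso

        sk = Lasso(alpha=alpha / (2 * 40), fit_intercept=False, max_iter=100000, tol=1e-12)
        sk.fit(X, y)
        ours = omtl_objective(X, y[:, None], fit.B, alpha)
        theirs = omtl_objective(X, y[:, None], sk.coef_[:, None], alpha)
        assert abs(ours - theirs) / theirs <= 1e-6

    def test_matches_convex_oracle(self, rng):
        for seed in range(5):
            local = np.random.default_rng(100 + seed)
            X = local.standard_normal((30, 6))
            Y = local.standard_normal((30, 4))
            alpha = float(2 * local.uniform(2, 10))
            fit = fit_omtl(X, Y, alpha, max_iter=20000, tol=1e-14)
            groups = [(np.arange(4), 1.0)]
            B_oracle = solve_group_objective_oracle(X, Y, groups, alpha)
            ours = omtl_objective(X, Y, fit.B, alpha)
            theirs = omtl_objective(X, Y, B_oracle, alpha)
            assert abs(ours - theirs) / theirs <= 1e-4

    def test_rows_zeroed_jointly(self, rng):
        X = rng.standard_normal((50, 8))
        B_true = np.zeros((8, 3))
        B_true[1] = [2, 2, 2]
        Y = X @ B_true + 0.01 * rng.standard_normal((50, 3))
        fit = fit_omtl(X, Y, 30.0, max_iter=5000, tol=1e-12)
        row_norms = np.linalg.norm(fit.B, axis=1)
        # a row is either all-zero or fully active across tasks
        for j in range(8):
            assert (row_norms[j] == 0) == np.all(fit.B[j] == 0)
        assert row_norms[1] > 0


class TestFitStl:
    def test_alpha_grid_has_11_values(self):
        assert len(DEFAULT_STL_ALPHA_GRID) == 11
        assert DEFAULT_STL_ALPHA_GRID[0] == 0.0
        assert DEFAULT_STL_ALPHA_GRID[-1] == 1.0

    def test_noiseless_sparse_recovery(self, rng):
        X = rng.standard_normal((60, 8))
        beta = np.zeros(8)
        beta[[1, 4]] = [2.0, -1.5]
        y = X @ beta
        fit = fit_stl(X, y[:, None], seed=0, eps=1e-7)
        assert np.abs(fit.B[:, 0] - beta).max() < 1e-3

    def test_constant_response_null_model(self, rng):
        X = rng.standard_normal((30, 4))
        Y = np.column_stack([np.ones(30), X @ np.array([1.0, 0, 0, 0])])
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_stl(X, Y, seed=0)
        assert np.all(fit.B[:, 0] == 0)

    def test_permuted_response_predicts_nothing(self, rng):
        X = rng.standard_normal((80, 5))
        y = X @ np.array([1.0, 2.0, 0, 0, 0]) + 0.1 * rng.standard_normal(80)
        y_perm = rng.permutation(y)
        fit = fit_stl(X[:60], y_perm[:60, None], seed=0)
        pred = X[60:] @ fit.B[:, 0]
        mse = float(((y_perm[60:] - pred) ** 2).mean())
        var = float(y_perm[60:].var())
        assert mse >= 0.7 * var  # no structure to exploit


class TestCrossValidateTree:
    def test_default_grid_21_values(self):
        assert len(DEFAULT_LAMBDA_GRID) == 21
        assert DEFAULT_LAMBDA_GRID[0] == 0.0
        assert DEFAULT_LAMBDA_GRID[-1] == 1.0
        steps = np.diff(DEFAULT_LAMBDA_GRID)
        assert np.allclose(steps, 0.05)

    def test_selected_minimizes_mean_loss(self, small_instance):
        X, Y, tree = small_instance
        cv = cross_validate_tree(X, Y, tree, lambda_grid=(0.0, 0.1, 0.5), folds=3, seed=0)
        assert cv.mean_losses[np.flatnonzero(cv.grid == cv.selected)[0]] == cv.mean_losses.min()

    def test_empty_grid_rejected(self, small_instance):
        X, Y, tree = small_instance
        with pytest.raises(ValueError):
            cross_validate_tree(X, Y, tree, lambda_grid=())

    def test_folds_partition_genes(self, small_instance):
        X, Y, tree = small_instance
        cv = cross_validate_tree(X, Y, tree, lambda_grid=(0.1,), folds=5, seed=3)
        assert cv.fold_assignment.shape == (30,)
        assert set(cv.fold_assignment.tolist()) == set(range(5))


class TestPredictEvaluate:
    def test_residuals_orthogonal_at_lambda_zero(self, small_instance):
        X, Y, tree = small_instance
        fit = fit_tree_guided(X, Y, tree, 0.0)
        resid = Y - X @ fit.B
        assert np.allclose(X.T @ resid, 0, atol=1e-9)

    def test_zero_input_gives_training_means(self, rng):
        Y_train = rng.standard_normal((30, 3)) * 2 + 5
        ys = Standardizer().fit(Y_train)
        fit = FitResult(B=rng.standard_normal((4, 3)), model_kind="tree", y_scaler=ys)
        out = predict(fit, np.zeros((2, 4)))
        assert np.allclose(out, Y_train.mean(axis=0), atol=1e-10)

    def test_linearity_in_standardized_space(self, rng):
        B = rng.standard_normal((4, 3))
        fit = FitResult(B=B, model_kind="tree")
        X1, X2 = rng.standard_normal((5, 4)), rng.standard_normal((5, 4))
        lhs = predict(fit, 2.0 * X1 + 3.0 * X2)
        rhs = 2.0 * predict(fit, X1) + 3.0 * predict(fit, X2)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_feature_count_mismatch(self, rng):
        fit = FitResult(B=rng.standard_normal((4, 3)), model_kind="tree")
        with pytest.raises(ValueError):
            predict(fit, np.zeros((2, 5)))

    def test_perfect_prediction(self, rng):
        Y = rng.standard_normal((10, 4))
        assert np.allclose(evaluate_per_cell(Y, Y), 1.0)

    def test_negated_prediction(self, rng):
        Y = rng.standard_normal((10, 4))
        assert np.allclose(evaluate_per_cell(-Y, Y), -1.0)

    def test_independent_noise_mean_near_zero(self, rng):
        rs = [
            evaluate_per_cell(rng.standard_normal((50, 20)), rng.standard_normal((50, 20))).mean()
            for _ in range(10)
        ]
        assert abs(np.mean(rs)) < 0.05

    def test_constant_prediction_is_nan(self, rng):
        Y_hat = np.column_stack([np.ones(10), rng.standard_normal(10)])
        Y = rng.standard_normal((10, 2))
        r = evaluate_per_cell(Y_hat, Y)
        assert np.isnan(r[0]) and np.isfinite(r[1])

    def test_too_few_genes(self, rng):
        with pytest.raises(ValueError):
            evaluate_per_cell(np.ones((2, 2)), np.ones((2, 2)))
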