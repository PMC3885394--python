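import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from whlfs.data import FeatureTable
from whlfs.solver import (
    default_lambda_grid,
    fit_all_pair_lasso,
    fit_path,
    fit_weak_hier_lasso,
    lambda_max,
    loss_value_grad,
    make_problem,
    objective_value,
    onerow_prox,
    predict,
)

from conftest import random_table


class TestLossValueGrad:
    def test_logistic_at_zero_is_ln2_for_balanced_outcome(self, rng):
        table = FeatureTable(
            rng.standard_normal((10, 3)),
            ["a", "b", "c"],
            ["M"] * 3,
            [0, 1] * 5,
        )
        problem = make_problem(table, "logistic")
        v, _ = loss_value_grad(problem, 0.0, np.zeros(3), np.zeros((3, 3)))
        assert v == pytest.approx(np.log(2), rel=1e-12)

    def test_squared_loss_zero_at_exact_fit(self, rng):
        table = random_table(rng, n=20, p=3)
        problem = make_problem(table, "squared")
        # eta == y exactly is not reachable via beta alone; check via the
        # definition: eta = y gives residual zero
        from whlfs.solver import _smooth_value

        assert _smooth_value(problem, problem.table.y.astype(float)) == 0.0

    @pytest.mark.parametrize("loss", ["logistic", "squared"])
    def test_gradient_matches_central_differences(self, rng, loss):
        table = random_table(rng, n=15, p=4)
        problem = make_problem(table, loss)
        p = problem.p
        beta0 = 0.3
        beta = rng.standard_normal(p) * 0.5
        Theta = rng.standard_normal((p, p)) * 0.2
        np.fill_diagonal(Theta, 0.0)
        v, (g0, gb, gT) = loss_value_grad(problem, beta0, beta, Theta)
        h = 1e-6

        def val(b0, b, T):
            return loss_value_grad(problem, b0, b, T)[0]

        num0 = (val(beta0 + h, beta, Theta) - val(beta0 - h, beta, Theta)) / (2 * h)
        assert g0 == pytest.approx(num0, rel=1e-6, abs=1e-9)
        for j in range(p):
            e = np.zeros(p)
            e[j] = h
            num = (val(beta0, beta + e, Theta) - val(beta0, beta - e, Theta)) / (2 * h)
            assert gb[j] == pytest.approx(num, rel=1e-6, abs=1e-9)
        for j, k in [(0, 1), (2, 3), (3, 0)]:
            E = np.zeros((p, p))
            E[j, k] = h
            num = (val(beta0, beta, Theta + E) - val(beta0, beta, Theta - E)) / (2 * h)
            assert gT[j, k] == pytest.approx(num, rel=1e-6, abs=1e-9)

    def test_nonfinite_parameters_rejected(self, rng):
        table = random_table(rng, n=10, p=2)
        problem = make_problem(table)
        with pytest.raises(ValueError, match="non-finite"):
            loss_value_grad(problem, np.inf, np.zeros(2), np.zeros((2, 2)))


class TestOnerowProx:
    def test_plain_soft_threshold_when_constraint_slack(self):
        bp, bm, th = onerow_prox(1.0, 0.0, np.zeros(4), lam=0.3, t=1.0)
        assert bp == pytest.approx(0.7)
        assert bm == 0.0
        assert np.all(th == 0)

    def test_identity_at_zero_penalty_with_slack_constraint(self):
        T = np.array([0.2, -0.3, 0.1])
        bp, bm, th = onerow_prox(0.5, 0.4, T, lam=0.0, t=1.0)
        assert bp == pytest.approx(0.5) and bm == pytest.approx(0.4)
        np.testing.assert_allclose(th, T, atol=1e-12)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            onerow_prox(np.nan, 0.0, np.zeros(2), 0.1, 1.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_output_always_feasible(self, seed):
        r = np.random.default_rng(seed)
        m = int(r.integers(1, 9))
        bp, bm, th = onerow_prox(
            r.normal(), r.normal(), r.normal(size=m), r.uniform(0, 2), r.uniform(0.01, 3)
        )
        assert bp >= 0 and bm >= 0
        assert np.abs(th).sum() <= bp + bm + 1e-9

    def test_matches_convex_oracle_on_random_instances(self):
        from _oracles import onerow_oracle

        r = np.random.default_rng(7)
        for _ in range(25):
            b_plus, b_minus = r.normal(), r.normal()
            T = r.normal(size=6)
            lam, t = r.uniform(0, 1.5), r.uniform(0.05, 2.0)
            bp, bm, th = onerow_prox(b_plus, b_minus, T, lam, t)
            mine = (
                (1 / (2 * t))
                * ((bp - b_plus) ** 2 + (bm - b_minus) ** 2 + np.sum((th - T) ** 2))
                + lam * (bp + bm)
                + 0.5 * lam * np.abs(th).sum()
            )
            assert mine <= onerow_oracle(b_plus, b_minus, T, lam, t) + 1e-9


class TestFitWeakHierLasso:
    def test_lambda_max_matches_bruteforce_bisection(self, rng):
        from _oracles import lambda_max_bisect

        table = random_table(rng, n=40, p=4)
        for loss in ["logistic", "squared"]:
            problem = make_problem(table, loss)
            analytic = lambda_max(problem)
            brute = lambda_max_bisect(
                problem, lambda pr, lam: fit_weak_hier_lasso(pr, lam, tol=1e-10)
            )
            assert brute == pytest.approx(analytic, rel=0.01)

    def test_above_lambda_max_gives_intercept_only_fit(self, rng):
        table = random_table(rng, n=40, p=5)
        problem = make_problem(table)
        fit = fit_weak_hier_lasso(problem, lambda_max(problem) * 1.01)
        assert np.abs(fit.beta).max() == 0
        assert np.abs(fit.Theta).max() == 0
        ybar = table.y.mean()
        assert fit.beta0 == pytest.approx(np.log(ybar / (1 - ybar)), abs=1e-4)

    def test_unpenalized_squared_fit_matches_least_squares(self, rng):
        table = random_table(rng, n=200, p=4)
        problem = make_problem(table, "squared")
        fit = fit_weak_hier_lasso(problem, 0.0, tol=1e-12, max_iter=20000)
        A = np.column_stack(
            [np.ones(table.n), problem.X_norm, problem.design.Z]
        )
        coef, *_ = np.linalg.lstsq(A, table.y.astype(float), rcond=None)
        w = fit.pair_weights(problem.design.pair_index)
        mine = np.concatenate([[fit.beta0], fit.beta, w])
        np.testing.assert_allclose(mine, coef, atol=1e-4)

    def test_objective_trace_non_increasing(self, rng):
        table = random_table(rng, n=50, p=6)
        problem = make_problem(table)
        fit = fit_weak_hier_lasso(problem, lambda_max(problem) * 0.05)
        diffs = np.diff(fit.objective_trace)
        assert np.all(diffs <= 1e-10)

    def test_invariants_hold_along_path(self, rng):
        table = random_table(rng, n=50, p=6)
        for loss in ["logistic", "squared"]:
            problem = make_problem(table, loss)
            for fit in fit_path(problem, default_lambda_grid(problem, 8)):
                fit.check_invariants()

    def test_permuting_features_permutes_fit(self, rng):
        table = random_table(rng, n=60, p=5)
        problem = make_problem(table)
        lam = lambda_max(problem) * 0.1
        fit = fit_weak_hier_lasso(problem, lam, tol=1e-11)
        perm = np.array([3, 0, 4, 1, 2])
        table2 = FeatureTable(
            table.X[:, perm],
            [table.feature_names[j] for j in perm],
            [table.feature_groups[j] for j in perm],
            table.y,
        )
        problem2 = make_problem(table2)
        fit2 = fit_weak_hier_lasso(problem2, lam, tol=1e-11)
        # the identified quantities are beta and the symmetrized pair
        # weights (the split of a pair weight across its two Theta rows is
        # not unique); compare those
        np.testing.assert_allclose(fit2.beta, fit.beta[perm], atol=1e-4)
        W1 = 0.5 * (fit.Theta + fit.Theta.T)
        W2 = 0.5 * (fit2.Theta + fit2.Theta.T)
        np.testing.assert_allclose(W2, W1[np.ix_(perm, perm)], atol=1e-4)

    def test_negative_lambda_rejected(self, small_table):
        problem = make_problem(small_table)
        with pytest.raises(ValueError):
            fit_weak_hier_lasso(problem, -0.1)


class TestFitPath:
    def test_grid_of_16_gives_16_fits(self, rng):
        table = random_table(rng, n=40, p=4)
        problem = make_problem(table)
        fits = fit_path(problem, default_lambda_grid(problem, 16))
        assert len(fits) == 16
        assert fits[0].lam == pytest.approx(lambda_max(problem))

    def test_first_fit_above_lambda_max_is_zero(self, rng):
        table = random_table(rng, n=40, p=4)
        problem = make_problem(table)
        lmax = lambda_max(problem)
        fits = fit_path(problem, [lmax * 1.01, lmax * 0.5])
        assert np.abs(fits[0].beta).max() == 0
        assert np.abs(fits[0].Theta).max() == 0

    def test_warm_start_never_worse_than_cold_start(self, rng):
        table = random_table(rng, n=50, p=5)
        problem = make_problem(table)
        grid = default_lambda_grid(problem, 6)
        warm = fit_path(problem, grid, tol=1e-9)
        for lam, wfit in zip(grid, warm):
            cold = fit_weak_hier_lasso(problem, lam, tol=1e-9)
            assert objective_value(problem, wfit) <= objective_value(
                problem, cold
            ) + 1e-8

    def test_empty_grid_rejected(self, small_table):
        problem = make_problem(small_table)
        with pytest.raises(ValueError, match="empty"):
            fit_path(problem, [])

    def test_non_decreasing_grid_rejected(self, small_table):
        problem = make_problem(small_table)
        with pytest.raises(ValueError, match="decreasing"):
            fit_path(problem, [0.1, 0.2])


class TestAllPairLasso:
    def test_large_penalty_gives_zero_fit(self, rng):
        table = random_table(rng, n=40, p=4)
        problem = make_problem(table, "squared")
        fit = fit_all_pair_lasso(problem, 10.0)
        assert np.abs(fit.beta).max() == 0 and np.abs(fit.Theta).max() == 0

    def test_matches_sklearn_coordinate_descent(self, rng):
        from sklearn.linear_model import Lasso

        table = random_table(rng, n=60, p=5)
        problem = make_problem(table, "squared")
        lam = lambda_max(problem) * 0.2
        fit = fit_all_pair_lasso(problem, lam, tol=1e-12)
        A = np.hstack([problem.X_norm, problem.design.Z])
        ref = Lasso(alpha=lam, fit_intercept=True, tol=1e-12, max_iter=100000)
        ref.fit(A, table.y)
        y = table.y

        def obj(b0, c):
            r = y - b0 - A @ c
            return 0.5 * np.mean(r**2) + lam * np.abs(c).sum()

        w = fit.pair_weights(problem.design.pair_index)
        mine = obj(fit.beta0, np.concatenate([fit.beta, w]))
        theirs = obj(ref.intercept_, ref.coef_)
        assert mine <= theirs + 1e-6

    def test_can_violate_hierarchy_on_interaction_only_signal(self):
        # outcome driven purely by the product x0*x1: the unconstrained
        # baseline picks the pair with no main effects, the hierarchical
        # model cannot
        r = np.random.default_rng(3)
        n = 300
        X = r.choice([-1.0, 1.0], size=(n, 4))
        y = (X[:, 0] * X[:, 1] > 0).astype(int)
        table = FeatureTable(X, list("abcd"), ["M"] * 4, y)
        problem = make_problem(table, "squared")
        lam = lambda_max(problem) * 0.5
        ap = fit_all_pair_lasso(problem, lam, tol=1e-10)
        budget = ap.beta_plus + ap.beta_minus
        rows = np.abs(ap.Theta).sum(axis=1)
        assert np.any(rows > budget + 1e-8), "baseline should break hierarchy"
        wh = fit_weak_hier_lasso(problem, lam, tol=1e-10)
        wh.check_invariants()


class TestPredict:
    def test_all_zero_fit_predicts_half_probability(self, rng):
        table = random_table(rng, n=30, p=3)
        problem = make_problem(table)
        fit = fit_weak_hier_lasso(problem, lambda_max(problem) * 1.5)
        fit.beta0 = 0.0
        _, _, prob = predict(fit, problem, table.X)
        np.testing.assert_allclose(prob, 0.5, atol=1e-12)

    def test_training_scores_reproduce_fitted_eta(self, rng):
        table = random_table(rng, n=40, p=4)
        problem = make_problem(table)
        fit = fit_weak_hier_lasso(problem, lambda_max(problem) * 0.1)
        scores, _, _ = predict(fit, problem, table.X, table.feature_names)
        w = fit.pair_weights(problem.design.pair_index)
        eta = fit.beta0 + problem.X_norm @ fit.beta + problem.design.Z @ w
        np.testing.assert_allclose(scores, eta, atol=1e-10)

    def test_intercept_sign_flip_flips_scores(self, rng):
        table = random_table(rng, n=20, p=3)
        problem = make_problem(table)
        fit = fit_weak_hier_lasso(problem, lambda_max(problem) * 1.5)
        fit.beta0 = 1.0
        s1, _, _ = predict(fit, problem, table.X)
        fit.beta0 = -1.0
        s2, _, _ = predict(fit, problem, table.X)
        np.testing.assert_allclose(s1, -s2, atol=1e-12)

    def test_column_mismatch_rejected(self, rng):
        table = random_table(rng, n=20, p=3)
        problem = make_problem(table)
        fit = fit_weak_hier_lasso(problem, 1.0)
        with pytest.raises(ValueError):
            predict(fit, problem, np.ones((2, 7)))
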