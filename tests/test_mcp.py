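"""MCP penalty, firm threshold, the path solver, and selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pshima import firm_threshold, fit_mcp_path, mcp_penalty, oracle_se, select_lambda


class TestPenalty:
    def test_zero(self):
        assert mcp_penalty(0.0, 1.0, 3.0) == 0.0

    def test_quadratic_region(self):
        assert mcp_penalty(0.5, 1.0, 3.0) == pytest.approx(0.5 - 0.25 / 6)

    def test_saturation(self):
        # flat at delta*lambda^2/2 beyond |b| = delta*lambda
        assert mcp_penalty(5.0, 1.0, 3.0) == pytest.approx(1.5)
        assert mcp_penalty(3.0, 1.0, 3.0) == pytest.approx(1.5)

    def test_continuous_at_knot(self):
        lam, delta = 0.7, 2.5
        knot = delta * lam
        assert mcp_penalty(knot - 1e-9, lam, delta) == pytest.approx(
            mcp_penalty(knot, lam, delta), abs=1e-6
        )

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            mcp_penalty(1.0, -0.1, 3.0)


class TestFirmThreshold:
    @pytest.mark.parametrize(
        "z, expected", [(0.8, 0.0), (2.0, 1.5), (4.0, 4.0), (-2.0, -1.5)]
    )
    def test_reference_points(self, z, expected):
        assert firm_threshold(z, 1.0, 3.0) == pytest.approx(expected)

    def test_delta_at_most_one_rejected(self):
        with pytest.raises(ValueError):
            firm_threshold(1.0, 1.0, 1.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        z=st.floats(-6, 6),
        lam=st.floats(0.05, 2.0),
        delta=st.floats(1.2, 8.0),
    )
    def test_is_argmin_of_scalar_objective(self, z, lam, delta):
        # brute-force 1-D minimization of 0.5*(b-z)^2 + p(b)
        grid = np.linspace(-8, 8, 16001)
        vals = 0.5 * (grid - z) ** 2 + mcp_penalty(grid, lam, delta)
        b = firm_threshold(z, lam, delta)
        obj_b = 0.5 * (b - z) ** 2 + mcp_penalty(b, lam, delta)
        assert obj_b <= vals.min() + 1e-6


def _objective(Y, X, M, beta, gamma, intercept, lam, delta):
    resid = Y - intercept - gamma * X - M @ beta
    n = len(Y)
    return resid @ resid / (2 * n) + mcp_penalty(
        np.asarray(beta) * np.std(M, axis=0), lam, delta
    ).sum()


class TestPathSolver:
    def test_unpenalized_limit_is_ols(self, rng):
        n, d = 80, 5
        M = rng.standard_normal((n, d))
        X = (rng.random(n) < 0.5).astype(float)
        Y = 0.3 * X + M @ np.array([1.0, -0.5, 0.0, 0.8, 0.2]) + 0.2 * rng.standard_normal(n)
        fits = fit_mcp_path(Y, X, M, lambda_grid=[1.0, 0.1, 0.0])
        D = np.column_stack([np.ones(n), X, M])
        coef, *_ = np.linalg.lstsq(D, Y, rcond=None)
        assert np.allclose(fits[-1].beta, coef[2:], atol=1e-6)
        assert fits[-1].gamma_hat == pytest.approx(coef[1], abs=1e-6)

    def test_orthonormal_design_matches_firm_threshold(self, rng):
        # columns orthonormalized => separable problem, closed-form solution
        n, d = 64, 4
        A = rng.standard_normal((n, d + 1))
        Q, _ = np.linalg.qr(A - A.mean(axis=0))
        Q = Q * np.sqrt(n)  # mean-0 columns with x'x/n == 1
        X, M = Q[:, 0], Q[:, 1:]
        truth = np.array([2.0, -0.8, 0.3, 0.05])
        Y = M @ truth
        lam = 0.5
        fits = fit_mcp_path(Y, X, M, lambda_grid=[lam], delta=3.0)
        z = M.T @ (Y - Y.mean()) / n
        expected = firm_threshold(z, lam, 3.0)
        assert np.allclose(fits[0].beta, expected, atol=1e-5)

    def test_beats_exhaustive_grid_oracle(self, rng):
        # 2-mediator instance: solver objective <= any point of a fine grid
        n = 60
        M = rng.standard_normal((n, 2))
        M[:, 1] = 0.6 * M[:, 0] + 0.8 * M[:, 1]
        X = (rng.random(n) < 0.5).astype(float)
        Y = 0.5 * X + 1.2 * M[:, 0] - 0.7 * M[:, 1] + 0.5 * rng.standard_normal(n)
        lam, delta = 0.3, 3.0
        fits = fit_mcp_path(Y, X, M, lambda_grid=[lam], delta=delta)
        fit = fits[0]

        sd = M.std(axis=0)

        def obj(b1, b2):
            beta = np.array([b1, b2])
            resid = Y - fit.intercept - fit.gamma_hat * X - M @ beta
            return resid @ resid / (2 * n) + mcp_penalty(beta * sd, lam, delta).sum()

        ours = obj(fit.beta[0], fit.beta[1])
        grid = np.arange(-2.0, 2.0, 0.01)
        vals = np.array([[obj(b1, b2) for b2 in grid] for b1 in grid])
        assert ours <= vals.min() + 1e-6

    def test_objective_nonincreasing_over_sweeps(self, rng):
        # monitored indirectly: the solution at each lambda cannot be worse
        # than the warm start it began from
        n, d = 100, 12
        M = rng.standard_normal((n, d))
        X = (rng.random(n) < 0.5).astype(float)
        Y = M[:, 0] * 1.5 + 0.4 * X + rng.standard_normal(n)
        fits = fit_mcp_path(Y, X, M, nlambda=20)
        sd = M.std(axis=0)
        for prev, cur in zip(fits, fits[1:]):
            resid_prev = Y - cur.intercept * 0 - prev.intercept - prev.gamma_hat * X - M @ prev.beta
            obj_warm = resid_prev @ resid_prev / (2 * n) + mcp_penalty(
                prev.beta * sd, cur.lam, cur.delta
            ).sum()
            resid_cur = Y - cur.intercept - cur.gamma_hat * X - M @ cur.beta
            obj_cur = resid_cur @ resid_cur / (2 * n) + mcp_penalty(
                cur.beta * sd, cur.lam, cur.delta
            ).sum()
            assert obj_cur <= obj_warm + 1e-8

    def test_large_delta_approaches_soft_threshold(self, rng):
        n, d = 64, 3
        A = rng.standard_normal((n, d + 1))
        Q, _ = np.linalg.qr(A - A.mean(axis=0))
        Q = Q * np.sqrt(n)
        X, M = Q[:, 0], Q[:, 1:]
        Y = M @ np.array([1.5, -0.6, 0.2])
        lam = 0.4
        fits = fit_mcp_path(Y, X, M, lambda_grid=[lam], delta=1e6)
        z = M.T @ (Y - Y.mean()) / n
        soft = np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)
        assert np.allclose(fits[0].beta, soft, atol=1e-4)

    def test_increasing_grid_rejected(self, rng):
        M = rng.standard_normal((30, 2))
        X = (rng.random(30) < 0.5).astype(float)
        with pytest.raises(ValueError):
            fit_mcp_path(M[:, 0], X, M, lambda_grid=[0.1, 0.5])


class TestSelectLambda:
    def test_single_fit_path(self, rng):
        M = rng.standard_normal((50, 3))
        X = (rng.random(50) < 0.5).astype(float)
        Y = M[:, 0] + rng.standard_normal(50)
        fits = fit_mcp_path(Y, X, M, lambda_grid=[0.2])
        assert select_lambda(fits, "bic") is fits[0]

    def test_null_model_mostly_selected_under_pure_noise(self):
        # BIC favors the empty support under pure noise; spurious entries
        # are rare and small (the joint test downstream removes the rest)
        empty = 0
        sizes = []
        runs = 50
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            M = rng.standard_normal((300, 20))
            X = (rng.random(300) < 0.5).astype(float)
            Y = rng.standard_normal(300)
            fit = select_lambda(fit_mcp_path(Y, X, M), "bic")
            empty += len(fit.support) == 0
            sizes.append(len(fit.support))
        assert empty / runs >= 0.5
        assert np.mean(sizes) <= 1.5

    def test_planted_signal_recovered(self):
        hits = 0
        runs = 50
        for seed in range(runs):
            rng = np.random.default_rng(1000 + seed)
            M = rng.standard_normal((300, 20))
            X = (rng.random(300) < 0.5).astype(float)
            Y = 2.0 * M[:, 7] + rng.standard_normal(300)
            fit = select_lambda(fit_mcp_path(Y, X, M), "bic")
            hits += 7 in fit.support
        assert hits / runs >= 0.95

    def test_bad_criterion(self, rng):
        M = rng.standard_normal((40, 2))
        X = (rng.random(40) < 0.5).astype(float)
        fits = fit_mcp_path(M[:, 0], X, M, lambda_grid=[0.2])
        with pytest.raises(ValueError):
            select_lambda(fits, "cp")


class TestOracleSe:
    def test_empty_support(self):
        assert oracle_se(np.ones(10), np.ones(10), np.empty((10, 0))).size == 0

    def test_matches_closed_form(self, rng):
        n = 60
        X = (rng.random(n) < 0.5).astype(float)
        M = rng.standard_normal((n, 3))
        Y = 0.5 * X + M @ np.array([1.0, -0.4, 0.2]) + 0.3 * rng.standard_normal(n)
        se = oracle_se(Y, X, M)
        D = np.column_stack([np.ones(n), X, M])
        coef, *_ = np.linalg.lstsq(D, Y, rcond=None)
        resid = Y - D @ coef
        sigma2 = resid @ resid / (n - D.shape[1])
        expected = np.sqrt(np.diag(sigma2 * np.linalg.inv(D.T @ D))[2:])
        assert np.allclose(se, expected, atol=1e-10)

    def test_ses_vanish_with_noise(self, rng):
        n = 60
        X = (rng.random(n) < 0.5).astype(float)
        M = rng.standard_normal((n, 2))
        Y = 0.5 * X + M @ np.array([1.0, -0.4])  # exact fit
        assert np.allclose(oracle_se(Y, X, M), 0.0, atol=1e-8)
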