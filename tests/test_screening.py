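"""Marginal estimators and sure independence screening."""

import numpy as np
import pytest
import statsmodels.api as sm

from pshima import (
    SimulationConfig,
    generate_dataset,
    marginal_beta_cov,
    marginal_beta_ps_covariate,
    marginal_beta_two_step,
    screen,
    sis_dimension,
)
from pshima.propensity import fit_propensity


class TestSisDimension:
    @pytest.mark.parametrize("n, p, expected", [(300, 1000, 106), (500, 10000, 161)])
    def test_formula(self, n, p, expected):
        assert sis_dimension(n, p) == expected

    def test_capped_at_p(self):
        assert sis_dimension(300, 50) == 50

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            sis_dimension(1)


class TestPsCovariate:
    def test_exact_interpolation(self, rng):
        # noiseless Y = 3*Mk: the fit interpolates and recovers 3 exactly
        n = 30
        Mk = rng.standard_normal(n)
        X = np.tile([0.0, 1.0], n // 2)
        S = rng.uniform(0.2, 0.8, n)
        beta, se = marginal_beta_ps_covariate(3.0 * Mk, X, Mk, S)
        assert beta == pytest.approx(3.0, abs=1e-8)

    def test_against_statsmodels(self, tiny_regression):
        X, S, M, Y = tiny_regression
        beta, se = marginal_beta_ps_covariate(Y, X, M[:, 0], S)
        fit = sm.OLS(Y, sm.add_constant(np.column_stack([X, M[:, 0], S]))).fit()
        assert beta == pytest.approx(fit.params[2], abs=1e-10)
        assert se == pytest.approx(fit.bse[2], abs=1e-10)

    def test_constant_mediator_flagged(self, tiny_regression):
        X, S, M, Y = tiny_regression
        beta, se = marginal_beta_ps_covariate(Y, X, np.ones(len(Y)), S)
        assert beta == 0.0 and np.isinf(se)


class TestTwoStep:
    def test_reduces_to_ols_with_unit_weights(self, rng):
        # unit weights, X orthogonal to Mk, noise-free Y = 2*Mk
        n = 200
        Mk = rng.standard_normal(n)
        X = np.tile([0.0, 1.0], n // 2)
        Y = 2.0 * Mk
        Mk = Mk - Mk.mean()  # enforce orthogonality in expectation is not enough
        X = X - 0  # keep binary
        beta, se = marginal_beta_two_step(2.0 * Mk, X, Mk, np.ones(n))
        assert beta == pytest.approx(2.0, abs=1e-8)

    def test_against_weighted_normal_equations_oracle(self, rng):
        # 8-row fixture: solve the weighted step-1 normal equations by
        # explicit inversion, then follow steps 2-3 with statsmodels
        Y = np.array([2.3, -0.4, 1.1, 0.8, 3.2, -1.0, 0.5, 2.8])
        X = np.array([1.0, 0, 1, 0, 1, 0, 0, 1])
        Mk = np.array([0.5, -1.2, 0.3, 0.8, 1.9, -0.6, 0.1, 1.4])
        w = np.array([1.2, 0.7, 2.0, 1.1, 0.5, 1.8, 0.9, 1.3])
        C = np.column_stack([np.ones(8), X, Mk])
        gamma_w = np.linalg.solve(C.T @ (w[:, None] * C), C.T @ (w * Y))[1]
        ek = Y - gamma_w * X
        oracle = sm.OLS(ek, sm.add_constant(Mk)).fit()
        beta, se = marginal_beta_two_step(Y, X, Mk, w)
        assert beta == pytest.approx(oracle.params[1], abs=1e-6)
        assert se == pytest.approx(oracle.bse[1], abs=1e-6)

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            marginal_beta_two_step(
                np.ones(4), np.array([0.0, 1, 0, 1]), np.ones(4), np.array([1.0, 0, 1, 1])
            )


class TestCovAdjusted:
    def test_empty_z_reduces(self, tiny_regression):
        X, S, M, Y = tiny_regression
        beta, se = marginal_beta_cov(Y, X, M[:, 1], np.empty((len(Y), 0)))
        fit = sm.OLS(Y, sm.add_constant(np.column_stack([X, M[:, 1]]))).fit()
        assert beta == pytest.approx(fit.params[2], abs=1e-10)

    def test_against_statsmodels(self, tiny_regression, rng):
        X, S, M, Y = tiny_regression
        Z = rng.standard_normal((len(Y), 3))
        beta, se = marginal_beta_cov(Y, X, M[:, 0], Z)
        fit = sm.OLS(Y, sm.add_constant(np.column_stack([X, M[:, 0], Z]))).fit()
        assert beta == pytest.approx(fit.params[2], abs=1e-10)
        assert se == pytest.approx(fit.bse[2], abs=1e-10)

    def test_collinear_z_rejected(self, tiny_regression):
        X, S, M, Y = tiny_regression
        Z = np.column_stack([X, X])  # collinear with exposure and itself
        with pytest.raises(ValueError):
            marginal_beta_cov(Y, X, M[:, 0], Z)


class TestScreen:
    def test_small_p_keeps_everything(self):
        ds = generate_dataset(SimulationConfig(n=300, p=50, seed=5))
        res = screen(ds, "COV")
        assert res.d == 50 and len(res.kept) == 50

    def test_ranking_matches_bruteforce(self):
        ds = generate_dataset(SimulationConfig(n=120, p=30, seed=6))
        ps = fit_propensity(ds.X, ds.Z)
        res = screen(ds, "PSR", ps, d=30)
        # brute force: standardized-scale |beta| via the scalar op
        sd = ds.M.std(axis=0)
        betas = np.array(
            [
                marginal_beta_ps_covariate(ds.Y, ds.X, ds.M[:, k], ps.scores)[0] * sd[k]
                for k in range(30)
            ]
        )
        expected = np.argsort(-np.abs(betas), kind="stable")
        assert np.array_equal(res.kept, expected)

    def test_strongest_mediator_always_screened(self):
        # mediator 8 carries the largest effect: present in every replicate
        for seed in range(1, 21):
            ds = generate_dataset(SimulationConfig(n=500, p=1000, seed=seed))
            ps = fit_propensity(ds.X, ds.Z)
            for method in ("PSR", "PSW", "COV"):
                res = screen(ds, method, ps)
                assert 7 in res.kept, f"seed {seed}, {method}"

    def test_sure_screening_rate(self):
        # screening almost never loses a moderate-or-strong mediator; only
        # the weakest two are occasionally displaced by the null bulk
        all8 = 0
        strong = 0
        R = 100
        for seed in range(1, R + 1):
            ds = generate_dataset(SimulationConfig(n=500, p=1000, seed=seed))
            ps = fit_propensity(ds.X, ds.Z)
            kept = set(screen(ds, "PSU", ps).kept.tolist())
            all8 += set(range(8)) <= kept
            strong += set(range(2, 8)) <= kept
        assert strong == R
        assert all8 / R >= 0.90

    def test_unknown_method(self, mode1_small):
        with pytest.raises(ValueError):
            screen(mode1_small, "XYZ")
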