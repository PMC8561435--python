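import numpy as np
import pytest
from scipy.optimize import minimize

from ccscreen import (
    CaseCohortData,
    CohortData,
    MarginalModelSpec,
    WeightProcess,
    solve_wee,
    variance_of_beta_j,
    weighted_score,
)
from ccscreen.wee import _RiskSetLayout, _score_info

from conftest import make_cohort


def textbook_partial_loglik(beta, X, Delta, Z):
    """Independent Breslow log partial likelihood (loop implementation)."""
    eta = Z @ np.asarray(beta)
    ll = 0.0
    for i in range(len(X)):
        if Delta[i] == 1:
            at_risk = X >= X[i]
            ll += eta[i] - np.log(np.sum(np.exp(eta[at_risk])))
    return ll


def weighted_pseudo_loglik(beta, cc, cols):
    """Independent weighted pseudo log partial likelihood (loop)."""
    wp = WeightProcess.from_data(cc)
    obs = cc.observed
    eta = np.where(obs, cc.Z_obs[:, cols] @ np.asarray(beta), 0.0)
    ll = 0.0
    for i in range(cc.n):
        if cc.Delta[i] == 1:
            t = cc.X[i]
            k = np.searchsorted(wp.event_times, t, side="right") - 1
            w = cc.Delta + (1 - cc.Delta) * cc.xi / wp.pi_hat_at[k]
            at_risk = (cc.X >= t) & obs
            ll += eta[i] - np.log(np.sum(w[at_risk] * np.exp(eta[at_risk])))
    return ll


class TestWeightedScore:
    def test_single_subject_saturated_score_is_zero(self):
        cc = CaseCohortData(
            X=np.array([1.0]),
            Delta=np.array([1]),
            xi=np.array([1]),
            Z_obs=np.array([[2.0]]),
        )
        U = weighted_score(MarginalModelSpec((), 0), np.array([0.7]), cc)
        assert U[0] == pytest.approx(0.0)

    def test_equals_standard_cox_score_on_full_cohort(self, small_cohort, full_cc):
        # all weights are 1, so the weighted score must equal the
        # gradient of the textbook log partial likelihood
        spec = MarginalModelSpec((0,), 2)
        beta = np.array([0.3, -0.2])
        U = weighted_score(spec, beta, full_cc)
        eps = 1e-6
        Z = small_cohort.Z[:, [0, 2]]
        for k in range(2):
            bp, bm = beta.copy(), beta.copy()
            bp[k] += eps
            bm[k] -= eps
            grad = (
                textbook_partial_loglik(bp, small_cohort.X, small_cohort.Delta, Z)
                - textbook_partial_loglik(bm, small_cohort.X, small_cohort.Delta, Z)
            ) / (2 * eps)
            assert U[k] == pytest.approx(grad, abs=1e-4)

    def test_constant_covariate_score_component_vanishes(self):
        rng = np.random.default_rng(0)
        n = 12
        Z = np.column_stack([np.full(n, 3.0), rng.standard_normal(n)])
        cc = CaseCohortData(
            X=rng.exponential(size=n) + 0.01,
            Delta=rng.integers(0, 2, n),
            xi=np.ones(n, dtype=int),
            Z_obs=Z,
        )
        for beta in ([0.0, 0.0], [1.2, -0.4]):
            U = weighted_score(MarginalModelSpec((1,), 0), np.array(beta)[::-1], cc)
            assert U[1] == pytest.approx(0.0, abs=1e-10)


class TestSolveWee:
    def test_matches_univariate_cox_mple_on_full_cohort(self, small_cohort, full_cc):
        spec = MarginalModelSpec((), 2)
        fit = solve_wee(spec, full_cc)
        res = minimize(
            lambda b: -textbook_partial_loglik(b, small_cohort.X, small_cohort.Delta,
                                               small_cohort.Z[:, [2]]),
            x0=[0.0],
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12},
        )
        assert fit.converged
        assert fit.beta_j == pytest.approx(res.x[0], abs=1e-6)

    def test_matches_brute_force_weighted_pseudo_likelihood(self, tiny_cc):
        # 10-subject case-cohort fixture, C = {0}, candidate 2:
        # grid search + polish on the weighted pseudo log-likelihood
        spec = MarginalModelSpec((0,), 2)
        with pytest.warns(UserWarning):
            fit = solve_wee(spec, tiny_cc)
        grid = np.linspace(-3, 3, 41)
        with pytest.warns(UserWarning):
            vals = [
                (weighted_pseudo_loglik([b0, b1], tiny_cc, [0, 2]), [b0, b1])
                for b0 in grid
                for b1 in grid
            ]
        start = max(vals)[1]
        with pytest.warns(UserWarning):
            res = minimize(
                lambda b: -weighted_pseudo_loglik(b, tiny_cc, [0, 2]),
                x0=start,
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12},
            )
        assert fit.converged
        assert np.allclose([fit.beta_cond[0], fit.beta_j], res.x, atol=1e-6)

    def test_score_is_zero_at_solution(self, tiny_cc, full_cc):
        for cc, cond in ((tiny_cc, (0,)), (full_cc, ()), (full_cc, (0, 1))):
            spec = MarginalModelSpec(cond, 2)
            fit = solve_wee(spec, cc)
            if fit.converged:
                U = weighted_score(spec, fit.params, cc)
                assert np.abs(U).max() <= 1e-8

    def test_null_model_estimates_centered_at_zero(self):
        # data generated with alpha = 0: mean of beta_hat over cohorts
        # should be statistically indistinguishable from 0
        betas = []
        for r in range(200):
            cohort = make_cohort(n=60, p=1, beta=(0.0,), seed=1000 + r)
            cc = CaseCohortData.from_full_cohort(cohort)
            fit = solve_wee(MarginalModelSpec((), 0), cc)
            if fit.converged:
                betas.append(fit.beta_j)
        betas = np.asarray(betas)
        assert abs(betas.mean()) < 3 * betas.std() / np.sqrt(len(betas))

    def test_degenerate_constant_covariate_flagged_not_raised(self):
        rng = np.random.default_rng(1)
        n = 15
        Z = np.column_stack([np.full(n, 2.0), rng.standard_normal(n)])
        cc = CaseCohortData(
            X=rng.exponential(size=n) + 0.01,
            Delta=np.ones(n, dtype=int),
            xi=np.ones(n, dtype=int),
            Z_obs=Z,
        )
        # the score is identically zero, but the information is singular:
        # the fit must come back with infinite variance (utility 0), not raise
        fit = solve_wee(MarginalModelSpec((), 0), cc)
        assert fit.sigma2_j == np.inf
        from ccscreen import utility

        assert utility(fit) == 0.0

    def test_jacobian_matches_information_matrix(self, tiny_cc):
        # -dU/dbeta from central differences vs the analytic information
        spec = MarginalModelSpec((0,), 2)
        beta = np.array([0.4, -0.2])
        with pytest.warns(UserWarning):
            layout = _RiskSetLayout(tiny_cc, spec.cond_set)
        Zj = layout.candidate_matrix(tiny_cc, np.array([spec.j]))
        _, info = _score_info(layout, Zj, beta[None, :], True)
        eps = 1e-5
        num = np.zeros((2, 2))
        for k in range(2):
            bp, bm = beta.copy(), beta.copy()
            bp[k] += eps
            bm[k] -= eps
            Up, _ = _score_info(layout, Zj, bp[None, :], False)
            Um, _ = _score_info(layout, Zj, bm[None, :], False)
            num[:, k] = -(Up[0] - Um[0]) / (2 * eps)
        assert np.allclose(num, info[0], atol=1e-4)

    def test_affine_invariance_of_candidate(self, full_cc):
        spec = MarginalModelSpec((0,), 2)
        base = solve_wee(spec, full_cc)
        # shift: beta and sigma2 unchanged
        shifted = CaseCohortData(
            X=full_cc.X, Delta=full_cc.Delta, xi=full_cc.xi,
            Z_obs=full_cc.Z_obs + np.array([0.0, 0.0, 5.0]), pi=1.0,
        )
        fs = solve_wee(spec, shifted)
        assert fs.beta_j == pytest.approx(base.beta_j, abs=1e-8)
        assert fs.sigma2_j == pytest.approx(base.sigma2_j, rel=1e-8)
        # scale by c: beta -> beta/c, sigma2 -> sigma2/c^2
        c = 4.0
        scaled = CaseCohortData(
            X=full_cc.X, Delta=full_cc.Delta, xi=full_cc.xi,
            Z_obs=full_cc.Z_obs * np.array([1.0, 1.0, c]), pi=1.0,
        )
        fc = solve_wee(spec, scaled)
        assert fc.beta_j == pytest.approx(base.beta_j / c, rel=1e-6)
        assert fc.sigma2_j == pytest.approx(base.sigma2_j / c**2, rel=1e-6)


class TestVarianceOfBetaJ:
    def test_scalar_reciprocal_when_unconditional(self, full_cc):
        fit = solve_wee(MarginalModelSpec((), 1), full_cc)
        assert variance_of_beta_j(fit) == pytest.approx(1.0 / fit.info[0, 0])

    def test_diagonal_info_bottom_right(self, full_cc):
        fit = solve_wee(MarginalModelSpec((0,), 2), full_cc)
        fit.info = np.diag([3.0, 5.0])
        assert variance_of_beta_j(fit) == pytest.approx(0.2)

    def test_singular_info_raises(self, full_cc):
        fit = solve_wee(MarginalModelSpec((0,), 2), full_cc)
        fit.info = np.zeros((2, 2))
        with pytest.raises(np.linalg.LinAlgError):
            variance_of_beta_j(fit)


class TestSpecValidation:
    def test_candidate_in_cond_set_rejected(self):
        with pytest.raises(ValueError):
            MarginalModelSpec((1, 2), 2)

    def test_duplicate_cond_indices_rejected(self):
        with pytest.raises(ValueError):
            MarginalModelSpec((1, 1), 0)
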