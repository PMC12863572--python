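import numpy as np
import pytest
from scipy import integrate, stats

from tsdea import (adjust_inputs, compute_environmental_component,
                   decompose_residuals, fit_slack_frontier, lr_test,
                   mixed_chi2_critical, SlackFrontier)
from tsdea.sfa import SFAFit, _halfnormal_loglik, SFAConvergenceError

from conftest import make_panel


def convolution_density(eps, sigma_u, sigma_v):
    """Independent oracle: numerically integrate the v + u convolution."""
    def integrand(u):
        return (2.0 / sigma_u * stats.norm.pdf(u / sigma_u)
                * stats.norm.pdf((eps - u) / sigma_v) / sigma_v)
    val, _ = integrate.quad(integrand, 0, np.inf)
    return val


def conditional_mean_u(eps, sigma_u, sigma_v):
    """Independent oracle: E[u | eps] by numerical integration."""
    def num(u):
        return u * (2.0 / sigma_u * stats.norm.pdf(u / sigma_u)
                    * stats.norm.pdf((eps - u) / sigma_v) / sigma_v)
    val, _ = integrate.quad(num, 0, np.inf)
    return val / convolution_density(eps, sigma_u, sigma_v)


def closed_form_logdensity(eps, sigma_u, sigma_v):
    """log h(eps) through the likelihood with an intercept-only design."""
    sigma2 = sigma_u ** 2 + sigma_v ** 2
    gamma = sigma_u ** 2 / sigma2
    params = np.array([0.0, np.log(sigma2),
                       np.log(gamma / (1 - gamma))])
    return _halfnormal_loglik(params, np.ones((1, 1)), np.array([eps]))


class TestCompositeDensity:
    @pytest.mark.parametrize("eps,su,sv", [
        (0.0, 1.0, 1.0), (0.7, 0.4, 0.2), (-0.5, 0.3, 0.6), (2.0, 1.5, 0.5),
    ])
    def test_closed_form_matches_quadrature(self, eps, su, sv):
        assert closed_form_logdensity(eps, su, sv) == pytest.approx(
            np.log(convolution_density(eps, su, sv)), abs=1e-8)

    def test_symmetric_point_value(self):
        # eps = 0, sigma_u = sigma_v = 1: h(0) = 2 phi(0/sqrt2)/sqrt2 * 1/2
        expected = 2 * stats.norm.pdf(0, scale=np.sqrt(2)) * 0.5
        assert np.exp(closed_form_logdensity(0.0, 1.0, 1.0)) == \
            pytest.approx(expected, abs=1e-12)


class TestJLMS:
    def test_closed_form_value_at_zero(self):
        u_hat, v_hat = decompose_residuals(np.array([0.0]), 1.0, 1.0)
        # sigma_* phi(0)/Phi(0) = (1/sqrt 2) * 2 phi(0)
        assert u_hat[0] == pytest.approx(0.5642, abs=1e-4)
        assert v_hat[0] == pytest.approx(-u_hat[0])

    @pytest.mark.parametrize("eps", [-1.0, -0.2, 0.0, 0.4, 1.5])
    def test_matches_conditional_mean_quadrature(self, eps):
        u_hat, _ = decompose_residuals(np.array([eps]), 0.4, 0.2)
        assert u_hat[0] == pytest.approx(
            conditional_mean_u(eps, 0.4, 0.2), abs=1e-6)

    def test_no_inefficiency_limit(self):
        eps = np.linspace(-2, 2, 9)
        u_hat, v_hat = decompose_residuals(eps, 0.0, 1.0)
        assert np.all(u_hat == 0)
        np.testing.assert_allclose(v_hat, eps)

    def test_monotone_in_residual(self):
        eps = np.linspace(-5, 5, 101)
        u_hat, _ = decompose_residuals(eps, 0.7, 0.3)
        assert np.all(np.diff(u_hat) >= -1e-12)
        assert np.all(u_hat >= 0)

    def test_deep_tail_never_nan(self):
        u_hat, v_hat = decompose_residuals(np.array([-60.0, 60.0]), 1.0, 1.0)
        assert np.isfinite(u_hat).all() and np.isfinite(v_hat).all()


class TestLRTest:
    def _fit(self, loglik, ols):
        z = np.zeros(1)
        return SFAFit(input_name="s", form="linear", beta=z, beta_se=z,
                      sigma_sq=1.0, gamma=0.5, loglik=loglik,
                      ols_loglik=ols, lr_stat=2 * (loglik - ols),
                      env_component=z, residuals=z, u_hat=z, v_hat=z,
                      boundary_gamma=False, converged=True)

    def test_identical_likelihoods(self):
        res = lr_test(self._fit(-100.0, -100.0))
        assert res.stat == 0.0
        assert not any(res.reject_at.values())

    def test_direct_arithmetic(self):
        res = lr_test(self._fit(-100.0, -110.0))
        assert res.stat == pytest.approx(20.0)
        assert res.reject_at[0.01]

    def test_negative_statistic_errors(self):
        with pytest.raises(SFAConvergenceError):
            lr_test(self._fit(-110.0, -100.0))

    def test_mixture_quantile_against_definition(self):
        # mixture tail: P(LR > c) = 0.5 P(chi2_1 > c); solve and verify
        for alpha in (0.1, 0.05, 0.01):
            c = mixed_chi2_critical(alpha)
            assert 0.5 * stats.chi2.sf(c, 1) == pytest.approx(alpha)
        assert mixed_chi2_critical(0.05) == pytest.approx(2.7055, abs=1e-4)


class TestFrontierFit:
    def test_pure_noise_reduces_to_ols(self):
        rng = np.random.default_rng(11)
        n = 500
        Z = rng.standard_normal((n, 2))
        y = 1.0 + Z @ [0.5, -0.3] + rng.normal(0, 0.3, n)
        fit = fit_slack_frontier(y, Z)
        assert fit.gamma < 0.1
        W = np.c_[np.ones(n), Z]
        beta_ols, *_ = np.linalg.lstsq(W, y, rcond=None)
        resid = y - W @ beta_ols
        se = np.sqrt(np.diag(np.linalg.inv(W.T @ W))
                     * (resid @ resid) / (n - 3))
        assert np.all(np.abs(fit.beta - beta_ols) <= 2 * se)

    def test_simulation_recovery(self):
        rng = np.random.default_rng(7)
        n = 300
        Z = rng.standard_normal((n, 1))
        y = (1.0 + 0.5 * Z[:, 0] + rng.normal(0, 0.2, n)
             + np.abs(rng.normal(0, 0.4, n)))
        fit = fit_slack_frontier(y, Z)
        assert abs(fit.gamma - 0.8) <= 0.15
        assert abs(fit.beta[1] - 0.5) <= 0.1
        assert fit.lr_stat >= 0
        assert fit.loglik >= fit.ols_loglik - 1e-6

    def test_gamma_stays_in_unit_interval(self):
        rng = np.random.default_rng(3)
        Z = rng.standard_normal((60, 1))
        y = 0.5 + np.abs(rng.normal(0, 1.0, 60))  # pure inefficiency
        fit = fit_slack_frontier(y, Z)
        assert 0 <= fit.gamma <= 1
        assert fit.gamma > 0.5  # inefficiency dominates the variance

    def test_rank_deficient_env_rejected(self):
        Z = np.ones((30, 2))  # collinear with the intercept
        with pytest.raises(ValueError, match="rank"):
            fit_slack_frontier(np.arange(30.0), Z)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="n > P"):
            fit_slack_frontier(np.ones(4), np.random.default_rng(0)
                               .standard_normal((4, 2)))

    def test_log_form_handles_zero_slacks(self):
        rng = np.random.default_rng(5)
        Z = np.c_[rng.uniform(0.5, 2.0, 120)]
        s = np.maximum(0.0, 0.5 * Z[:, 0] + rng.normal(0, 0.4, 120)
                       + np.abs(rng.normal(0, 0.5, 120)) - 0.5)
        assert (s == 0).any()
        fit = fit_slack_frontier(s, Z, form="log")
        assert np.isfinite(fit.loglik)
        assert np.isfinite(fit.env_component).all()


class TestEnvironmentalComponent:
    def _fit(self, beta, form="linear"):
        z = np.zeros(1)
        return SFAFit(input_name="s", form=form, beta=np.asarray(beta, float),
                      beta_se=z, sigma_sq=1.0, gamma=0.5, loglik=0.0,
                      ols_loglik=0.0, lr_stat=0.0, env_component=z,
                      residuals=z, u_hat=z, v_hat=z, boundary_gamma=False,
                      converged=True)

    def test_zero_coefficients_give_zero(self):
        f = compute_environmental_component(np.ones((4, 2)), self._fit([0, 0, 0]))
        np.testing.assert_allclose(f, 0.0)

    def test_dot_product_arithmetic(self):
        f = compute_environmental_component(np.array([[2.0]]),
                                            self._fit([1.0, 0.5]))
        assert f[0] == pytest.approx(2.0)

    def test_permutation_equivariance(self, rng):
        Z = rng.standard_normal((6, 3))
        fit = self._fit([0.3, 1.0, -0.5, 0.2])
        f = compute_environmental_component(Z, fit)
        perm = rng.permutation(6)
        np.testing.assert_allclose(
            compute_environmental_component(Z[perm], fit), f[perm])

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            compute_environmental_component(np.ones((3, 2)), self._fit([0, 1]))


class TestAdjustInputs:
    def _fit_with(self, f, v):
        f = np.asarray(f, float)
        v = np.asarray(v, float)
        z = np.zeros_like(f)
        return SFAFit(input_name="s", form="linear", beta=np.zeros(1),
                      beta_se=np.zeros(1), sigma_sq=1.0, gamma=0.5,
                      loglik=0.0, ols_loglik=0.0, lr_stat=0.0,
                      env_component=f, residuals=f + v, u_hat=z, v_hat=v,
                      boundary_gamma=False, converged=True)

    def test_worked_example(self):
        panel = make_panel([[10.0], [20.0]], [[1.0], [1.0]])
        adj = adjust_inputs(panel, [self._fit_with([2.0, 5.0], [0.1, -0.1])])
        np.testing.assert_allclose(adj.X_adj[:, 0], [13.0, 20.2])
        np.testing.assert_allclose(adj.env_adjustment[:, 0], [3.0, 0.0])
        np.testing.assert_allclose(adj.noise_adjustment[:, 0], [0.0, 0.2])

    def test_homogeneous_environment_is_noop(self):
        panel = make_panel([[10.0], [20.0]], [[1.0], [1.0]])
        adj = adjust_inputs(panel, [self._fit_with([4.0, 4.0], [0.3, 0.3])])
        np.testing.assert_allclose(adj.X_adj, panel.X)

    def test_max_anchored_dmu_unadjusted(self):
        panel = make_panel([[10.0], [20.0], [30.0]], [[1.0]] * 3)
        adj = adjust_inputs(panel, [self._fit_with([1, 5, 2], [0.0, 0.4, 0.1])])
        assert adj.env_adjustment[1, 0] == 0 and adj.noise_adjustment[1, 0] == 0
        assert adj.X_adj[1, 0] == panel.X[1, 0]

    def test_adjustments_nonnegative_and_monotone(self):
        panel = make_panel([[10.0], [20.0], [5.0]], [[1.0]] * 3)
        adj = adjust_inputs(panel, [self._fit_with([3, -1, 0], [0.2, 0, -0.2])])
        assert np.all(adj.X_adj >= panel.X - 1e-12)

    def test_wrong_fit_count_rejected(self):
        panel = make_panel([[1.0, 2.0]], [[1.0]])
        with pytest.raises(ValueError, match="one fit per input"):
            adjust_inputs(panel, [self._fit_with([0.0], [0.0])])

    def test_translation_invariance_of_linear_form(self):
        rng = np.random.default_rng(21)
        n = 150
        Z = rng.standard_normal((n, 2))
        s = (1.0 + Z @ [0.5, -0.4] + rng.normal(0, 0.2, n)
             + np.abs(rng.normal(0, 0.4, n)))
        panel = make_panel(np.c_[rng.uniform(5, 10, n)],
                           np.ones((n, 1)), Z=Z)
        fit_a = fit_slack_frontier(s, Z)
        Zc = Z.copy()
        Zc[:, 0] += 7.0
        fit_b = fit_slack_frontier(s, Zc)
        adj_a = adjust_inputs(panel, [fit_a])
        adj_b = adjust_inputs(panel, [fit_b])
        np.testing.assert_allclose(adj_b.env_adjustment,
                                   adj_a.env_adjustment, atol=1e-4)


def test_estimator_predict_matches_env_component(rng):
    Z = rng.standard_normal((200, 2))
    s = 2.0 + Z @ [1.0, -0.5] + rng.normal(0, 0.3, 200) \
        + np.abs(rng.normal(0, 0.5, 200))
    est = SlackFrontier().fit(Z, s)
    np.testing.assert_allclose(est.predict(Z), est.env_component_)
    fit = est.result_()
    np.testing.assert_allclose(
        compute_environmental_component(Z, fit), fit.env_component)
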