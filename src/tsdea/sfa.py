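"""Stochastic-frontier regression of input slacks on environmental
variables, and the environmental/noise neutralization of inputs.

Stage 2 of a three-stage DEA explains each input slack ``s_k`` by the
environmental covariates ``Z`` through a frontier model with composite
error

    s_k,i = f(Z_i; beta) + v_i + u_i,
    v ~ N(0, sigma_v^2),   u ~ |N(0, sigma_u^2)|  (half-normal),

estimated by maximum likelihood.  The one-sided term ``u`` carries
managerial waste (it inflates slack, the cost-frontier sign), ``v`` is
statistical noise, and ``gamma = sigma_u^2 / (sigma_u^2 + sigma_v^2)``
measures the inefficiency share of the composite variance.  The
composite density is

    h(eps) = (2/sigma) * phi(eps/sigma) * Phi(eps*lambda/sigma),

with ``sigma^2 = sigma_u^2 + sigma_v^2`` and ``lambda = sigma_u/sigma_v``.

The composite residual is split into its parts with the JLMS conditional
mean ``E[u|eps] = sigma_* (phi(a)/Phi(a) + a)``, ``a = eps*lambda/sigma``,
``sigma_* = sigma_u sigma_v / sigma``; the noise estimate is
``v_hat = eps_hat - E[u|eps_hat]``.  Inputs are then neutralized by
adding, per DMU and input, the shortfall from the least favourable
environment and from the worst noise draw:

    x_adj = x + [max_i f(Z_i) - f(Z_i)] + [max_i v_hat_i - v_hat_i],

which places every DMU in a common (worst-case) environment so that the
stage-3 DEA rerun reflects managerial performance only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import log_ndtr
from sklearn.base import BaseEstimator

from .panel import DMUPanel

__all__ = [
    "SlackFrontier",
    "SFAFit",
    "AdjustedPanel",
    "LRTestResult",
    "fit_slack_frontier",
    "lr_test",
    "mixed_chi2_critical",
    "decompose_residuals",
    "compute_environmental_component",
    "adjust_inputs",
]

#: gamma multistart grid (the gamma likelihood is often multimodal).
GAMMA_GRID = (0.05, 0.3, 0.6, 0.8, 0.95)
_GAMMA_EPS = 1e-9
_TWO_OVER_PI = 2.0 / np.pi


class SFAConvergenceError(RuntimeError):
    """MLE failed to converge after the multistart sweep."""


# ---------------------------------------------------------------- likelihood

def _halfnormal_loglik(params: np.ndarray, W: np.ndarray, y: np.ndarray) -> float:
    """Log-likelihood of the cost-sign half-normal composite error model.

    ``params`` = (beta, log sigma^2, logit gamma) in the unconstrained
    internal coordinates.
    """
    p = W.shape[1]
    beta = params[:p]
    sigma2 = np.exp(params[p])
    gamma = _expit_clipped(params[p + 1])
    sigma = np.sqrt(sigma2)
    lam = np.sqrt(gamma / (1.0 - gamma))
    eps = y - W @ beta
    z = eps / sigma
    # log h = log 2 - log sigma + log phi(z) + log Phi(lam z)
    ll = (np.log(2.0) - np.log(sigma)
          + stats.norm.logpdf(z) + log_ndtr(lam * z))
    return float(ll.sum())


def _expit_clipped(z: float) -> float:
    g = 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))
    return float(np.clip(g, _GAMMA_EPS, 1.0 - _GAMMA_EPS))


def _ols_loglik(resid: np.ndarray) -> float:
    n = len(resid)
    s2 = float(resid @ resid) / n  # ML variance
    return -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)


def _numerical_hessian(fun, x: np.ndarray) -> np.ndarray:
    k = len(x)
    H = np.empty((k, k))
    h = 1e-5 * (1.0 + np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej)
                - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


# ---------------------------------------------------------------- results

@dataclass
class SFAFit:
    """Fitted slack frontier for one input column.

    ``beta`` holds the intercept first, then one coefficient per
    environmental covariate.  ``env_component`` is ``f(Z; beta_hat)`` in
    slack units, ``u_hat = E[u|eps]`` and ``v_hat = eps - u_hat``.
    """

    input_name: str
    form: str
    beta: np.ndarray
    beta_se: np.ndarray
    sigma_sq: float
    gamma: float
    loglik: float
    ols_loglik: float
    lr_stat: float
    env_component: np.ndarray
    residuals: np.ndarray
    u_hat: np.ndarray
    v_hat: np.ndarray
    boundary_gamma: bool
    converged: bool
    env_names: list[str] = field(default_factory=list)
    log_z_cols: tuple[int, ...] = ()

    @property
    def sigma_u(self) -> float:
        return float(np.sqrt(self.gamma * self.sigma_sq))

    @property
    def sigma_v(self) -> float:
        return float(np.sqrt((1.0 - self.gamma) * self.sigma_sq))

    def t_values(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.beta_se


@dataclass
class LRTestResult:
    """One-sided LR test of gamma = 0 against the half-normal frontier.

    The null puts gamma on the boundary, so the statistic is compared
    with the 50:50 mixture of a point mass at 0 and chi-square(1)."""

    stat: float
    pvalue: float
    reject_at: dict[float, bool]


def mixed_chi2_critical(alpha: float, df: int = 1) -> float:
    """Critical value of the 1/2 chi2_0 + 1/2 chi2_df mixture."""
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5) for the mixture test")
    return float(stats.chi2.ppf(1.0 - 2.0 * alpha, df))


def lr_test(fit: SFAFit, ols_loglik: float | None = None,
            levels: tuple[float, ...] = (0.1, 0.05, 0.01)) -> LRTestResult:
    """Likelihood-ratio test for the presence of the inefficiency term."""
    ll0 = fit.ols_loglik if ols_loglik is None else ols_loglik
    stat = 2.0 * (fit.loglik - ll0)
    if stat < -1e-6:
        raise SFAConvergenceError(
            f"negative LR statistic {stat:.3g}: frontier likelihood below "
            "the OLS null indicates a failed optimization")
    stat = max(stat, 0.0)
    pvalue = 0.5 * stats.chi2.sf(stat, 1) if stat > 0 else 1.0
    return LRTestResult(
        stat=stat, pvalue=pvalue,
        reject_at={a: stat > mixed_chi2_critical(a) for a in levels})


def decompose_residuals(eps: np.ndarray, sigma_u: float,
                        sigma_v: float) -> tuple[np.ndarray, np.ndarray]:
    """JLMS split of composite residuals into (E[u|eps], v_hat).

    Cost-frontier sign: larger residuals mean more inefficiency.  The
    normal-cdf ratio is evaluated in log space, so deep-tail residuals
    never produce NaN.
    """
    eps = np.asarray(eps, float)
    if sigma_u <= 0:
        return np.zeros_like(eps), eps.copy()
    sigma = np.hypot(sigma_u, sigma_v)
    if sigma_v == 0:
        u = np.maximum(eps, 0.0)
        return u, eps - u
    lam = sigma_u / sigma_v
    sig_star = sigma_u * sigma_v / sigma
    a = eps * lam / sigma
    mills = np.exp(stats.norm.logpdf(a) - log_ndtr(a))
    u_hat = sig_star * (mills + a)
    u_hat = np.maximum(u_hat, 0.0)
    return u_hat, eps - u_hat


# ---------------------------------------------------------------- estimator

class SlackFrontier(BaseEstimator):
    """Half-normal stochastic frontier of one input slack on environment.

    Parameters
    ----------
    form : {"linear", "log"}
        ``linear`` regresses the raw slack on Z.  ``log`` (Cobb–Douglas
        style) regresses ``log1p(slack)`` on Z with strictly positive
        covariate columns log-transformed; ``log1p`` keeps zero slacks
        (common in DEA) in the sample.
    gamma_grid : multistart grid for the inefficiency share gamma.

    Attributes (after ``fit(Z, s)``)
    --------------------------------
    beta_, beta_se_, sigma_sq_, gamma_, loglik_, ols_loglik_, lr_stat_,
    env_component_, residuals_, u_hat_, v_hat_, boundary_gamma_.
    """

    def __init__(self, form: str = "linear",
                 gamma_grid: tuple[float, ...] = GAMMA_GRID,
                 input_name: str = "slack"):
        self.form = form
        self.gamma_grid = gamma_grid
        self.input_name = input_name

    # -- design helpers ----------------------------------------------
    def _design(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, float))
        if self.form == "log":
            Z = Z.copy()
            for j in self._log_cols_:
                Z[:, j] = np.log(Z[:, j])
        return np.c_[np.ones(len(Z)), Z]

    def fit(self, Z, s):
        if self.form not in ("linear", "log"):
            raise ValueError("form must be 'linear' or 'log'")
        Z = np.atleast_2d(np.asarray(Z, float))
        s = np.asarray(s, float).ravel()
        n, P = Z.shape
        if len(s) != n:
            raise ValueError("slack vector and Z disagree in length")
        if n <= P + 2:
            raise ValueError(f"need n > P+2 observations, got n={n}, P={P}")
        self._log_cols_ = tuple(
            j for j in range(P) if self.form == "log" and (Z[:, j] > 0).all())
        y = np.log1p(s) if self.form == "log" else s
        W = self._design(Z)
        if np.linalg.matrix_rank(W) < W.shape[1]:
            raise ValueError("environmental design matrix is rank-deficient")

        beta_ols, *_ = np.linalg.lstsq(W, y, rcond=None)
        resid = y - W @ beta_ols
        s2_ols = max(float(resid @ resid) / n, 1e-12)
        self.ols_loglik_ = _ols_loglik(resid)

        nll = lambda p: -_halfnormal_loglik(p, W, y)
        best = None
        for g0 in self.gamma_grid:
            sigma2_0 = s2_ols / (1.0 - _TWO_OVER_PI * g0)
            b0 = beta_ols.copy()
            b0[0] -= np.sqrt(g0 * sigma2_0 * _TWO_OVER_PI)  # E[u] shift
            x0 = np.r_[b0, np.log(sigma2_0), np.log(g0 / (1 - g0))]
            res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                    options={"maxiter": 500, "ftol": 1e-12,
                                             "gtol": 1e-8})
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise SFAConvergenceError(
                "slack-frontier MLE diverged on every multistart")
        p = W.shape[1]
        self.beta_ = best.x[:p]
        self.sigma_sq_ = float(np.exp(best.x[p]))
        self.gamma_ = _expit_clipped(best.x[p + 1])
        self.loglik_ = -float(best.fun)
        self.boundary_gamma_ = self.gamma_ > 0.999 or self.gamma_ < 1e-3
        self.converged_ = bool(best.success) or self.boundary_gamma_
        self.lr_stat_ = max(0.0, 2.0 * (self.loglik_ - self.ols_loglik_))

        # standard errors from the numerical Hessian (delta method for
        # sigma^2 and gamma); boundary fits get NaN rather than the
        # meaningless huge t-values a flat likelihood produces
        self.beta_se_ = np.full(p, np.nan)
        if not self.boundary_gamma_:
            try:
                H = _numerical_hessian(nll, best.x)
                cov = np.linalg.inv(H)
                d = np.diag(cov)
                if (d[:p] > 0).all():
                    self.beta_se_ = np.sqrt(d[:p])
            except np.linalg.LinAlgError:
                pass

        eta = W @ self.beta_
        self.residuals_ = y - eta
        su, sv = (np.sqrt(self.gamma_ * self.sigma_sq_),
                  np.sqrt((1 - self.gamma_) * self.sigma_sq_))
        self.u_hat_, self.v_hat_ = decompose_residuals(self.residuals_, su, sv)
        self.env_component_ = np.expm1(eta) if self.form == "log" else eta
        self._eta_ = eta
        return self

    def predict(self, Z) -> np.ndarray:
        """Environmental component f(Z; beta_hat) in slack units."""
        eta = self._design(Z) @ self.beta_
        return np.expm1(eta) if self.form == "log" else eta

    def result_(self) -> SFAFit:
        return SFAFit(
            input_name=self.input_name, form=self.form,
            beta=self.beta_, beta_se=self.beta_se_,
            sigma_sq=self.sigma_sq_, gamma=self.gamma_,
            loglik=self.loglik_, ols_loglik=self.ols_loglik_,
            lr_stat=self.lr_stat_, env_component=self.env_component_,
            residuals=self.residuals_, u_hat=self.u_hat_, v_hat=self.v_hat_,
            boundary_gamma=self.boundary_gamma_, converged=self.converged_,
            log_z_cols=self._log_cols_)


def fit_slack_frontier(slacks_k: np.ndarray, Z: np.ndarray,
                       form: str = "linear",
                       input_name: str = "slack") -> SFAFit:
    """Fit the half-normal slack frontier for one input column."""
    est = SlackFrontier(form=form, input_name=input_name).fit(Z, slacks_k)
    return est.result_()


def compute_environmental_component(Z: np.ndarray, fit: SFAFit) -> np.ndarray:
    """f(Z; beta_hat) per DMU, in slack units."""
    Z = np.atleast_2d(np.asarray(Z, float))
    if Z.shape[1] != len(fit.beta) - 1:
        raise ValueError("Z column count does not match the fitted beta")
    Zt = Z.copy()
    for j in fit.log_z_cols:
        Zt[:, j] = np.log(Zt[:, j])
    eta = fit.beta[0] + Zt @ fit.beta[1:]
    return np.expm1(eta) if fit.form == "log" else eta


# ---------------------------------------------------------------- adjustment

@dataclass
class AdjustedPanel:
    """Panel with environmentally neutralized inputs and the audit trail.

    ``X_adj = X + env_adjustment + noise_adjustment`` with both
    adjustment matrices nonnegative by max-anchoring: the DMU in the
    least favourable environment (largest fitted env component) and
    with the largest noise draw is left unadjusted on that input.
    """

    panel: DMUPanel
    X_adj: np.ndarray
    env_adjustment: np.ndarray
    noise_adjustment: np.ndarray
    fits: list[SFAFit]

    def to_panel(self) -> DMUPanel:
        return self.panel.with_inputs(self.X_adj)


def _noise_in_slack_units(fit: SFAFit) -> np.ndarray:
    """v_hat expressed in the units of the raw slack.

    Linear form: v_hat already lives on the slack scale.  Log form:
    the fit decomposes residuals of log1p(slack); the noise contribution
    on the original scale is the difference of back-transformed
    predictors with and without the noise term.
    """
    if fit.form == "linear":
        return fit.v_hat
    eta = np.log1p(np.maximum(fit.env_component, -1 + 1e-12))
    return np.expm1(eta + fit.v_hat) - np.expm1(eta)


def adjust_inputs(panel: DMUPanel, fits: list[SFAFit]) -> AdjustedPanel:
    """Neutralize environment and noise in every input column.

    Per input k:  ``x_adj = x + [max f - f] + [max v_hat - v_hat]``.
    """
    if len(fits) != panel.n_inputs:
        raise ValueError(
            f"need one fit per input column ({panel.n_inputs}), got {len(fits)}")
    n, K = panel.X.shape
    env_adj = np.empty((n, K))
    noise_adj = np.empty((n, K))
    for k, fit in enumerate(fits):
        f = np.asarray(fit.env_component, float)
        v = _noise_in_slack_units(fit)
        if len(f) != n or len(v) != n:
            raise ValueError(f"fit for input {k} has wrong length")
        env_adj[:, k] = f.max() - f
        noise_adj[:, k] = v.max() - v
    X_adj = panel.X + env_adj + noise_adj
    bad = ~np.isfinite(X_adj)
    if bad.any():
        i, k = np.argwhere(bad)[0]
        raise ValueError(
            f"non-finite adjusted input for DMU {panel.dmu_id[i]!r}, "
            f"input column {panel.input_names[k]!r}")
    return AdjustedPanel(panel=panel, X_adj=X_adj, env_adjustment=env_adj,
                         noise_adjustment=noise_adj, fits=list(fits))
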