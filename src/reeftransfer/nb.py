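"""Negative-binomial count regression (NB2, log link), with and without a
single group-level (reef) random intercept.

``NegativeBinomialGLM`` alternates IRLS for the coefficients (via the
statsmodels GLM machinery with the NB family at fixed dispersion) with
scalar maximum-likelihood updates of the dispersion theta — the classic
glm.nb algorithm.  ``NegativeBinomialGLMM`` adds one Gaussian random
intercept per group, integrated out by a Laplace approximation: per-group
univariate Newton mode-finding plus the log-curvature correction.  Both
follow the sklearn estimator contract (``fit``/``predict``/``get_params``)
and expose fitted attributes with trailing underscores.

Parameterisation: variance = mu + mu^2/theta.  The dispersion theta counts
as one estimated parameter in ``k_``; the random-intercept variance counts
as one more.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "NegativeBinomialGLM",
    "NegativeBinomialGLMM",
    "fit_poisson_glm",
    "dispersion_statistic",
    "nb2_loglik",
]

_MIN_LOG_THETA, _MAX_LOG_THETA = np.log(1e-3), np.log(1e7)


def _as_design(X) -> tuple[np.ndarray, list[str]]:
    """Prepend an intercept column; keep term names if X is a DataFrame."""
    if isinstance(X, pd.DataFrame):
        names = ["Intercept", *X.columns]
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        names = ["Intercept", *(f"x{i}" for i in range(arr.shape[1]))]
    return np.column_stack([np.ones(len(arr)), arr]), names


def _check_counts(y) -> np.ndarray:
    y = np.asarray(y)
    if y.ndim != 1:
        raise ValueError("response must be a 1-d count vector")
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("response must contain non-negative integer counts")
    return y.astype(float)


def nb2_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """NB2 log-likelihood, summed over observations."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    ll = (special.gammaln(y + theta) - special.gammaln(theta) - special.gammaln(y + 1)
          + theta * np.log(theta) + y * np.log(mu) - (y + theta) * np.log(theta + mu))
    return float(ll.sum())


def _nb_deviance(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    y = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y + theta) * np.log((y + theta) / (mu + theta))))


def _mle_theta(y: np.ndarray, mu: np.ndarray, theta0: float) -> float:
    """Maximise the NB2 log-likelihood over theta at fixed mu."""
    res = optimize.minimize_scalar(
        lambda lt: -nb2_loglik(y, mu, np.exp(lt)),
        bounds=(_MIN_LOG_THETA, _MAX_LOG_THETA),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(np.exp(res.x))


def _moment_theta(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments start: solve var = mu + mu^2/theta in aggregate."""
    resid2 = (y - mu) ** 2 - mu
    denom = float(np.sum(mu**2))
    if denom <= 0:
        return 1.0
    excess = float(np.sum(resid2)) / denom
    return float(np.clip(1.0 / excess if excess > 1e-8 else 1e6, 1e-3, 1e6))


class NegativeBinomialGLM(RegressorMixin, BaseEstimator):
    """NB2 regression with log link; joint MLE of coefficients and theta.

    Parameters
    ----------
    tol : float
        Convergence on the relative log-likelihood change between
        theta/beta alternations.
    max_iter : int
        Maximum alternations.
    theta_start : float or None
        Initial dispersion; None uses a method-of-moments estimate from a
        Poisson fit.

    Attributes (after ``fit``)
    --------------------------
    coef_, bse_ : arrays including the intercept (position 0)
    theta_ : float           NB2 dispersion
    loglik_ : float          maximised log-likelihood
    k_ : int                 parameter count (len(coef_) + 1 for theta)
    n_ : int                 observations
    fitted_ : array          response-scale fitted values
    deviance_, null_deviance_ : NB deviances at theta_
    converged_ : bool
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 200,
                 theta_start: float | None = None):
        self.tol = tol
        self.max_iter = max_iter
        self.theta_start = theta_start

    def fit(self, X, y):
        y = _check_counts(y)
        design, names = _as_design(X)
        if len(design) != len(y):
            raise ValueError("X and y have different lengths")
        if np.linalg.matrix_rank(design) < design.shape[1]:
            bad = _collinear_columns(design, names)
            raise ValueError(f"design is rank deficient; suspect columns: {bad}")
        self.term_names_ = names

        pois = sm.GLM(y, design, family=sm.families.Poisson()).fit()
        mu = np.asarray(pois.fittedvalues)
        theta = self.theta_start if self.theta_start is not None else _moment_theta(y, mu)

        ll_old, params, trace = -np.inf, np.asarray(pois.params), []
        converged = False
        for it in range(self.max_iter):
            theta = _mle_theta(y, mu, theta)
            nbfam = sm.families.NegativeBinomial(alpha=1.0 / theta)
            res = sm.GLM(y, design, family=nbfam).fit(
                start_params=params, maxiter=300, tol=1e-12
            )
            params = np.asarray(res.params)
            mu = np.asarray(res.fittedvalues)
            ll = nb2_loglik(y, mu, theta)
            trace.append(ll)
            if abs(ll - ll_old) < self.tol * (abs(ll) + 1.0):
                converged = True
                break
            ll_old = ll
        if not converged:
            raise RuntimeError(
                f"NB GLM did not converge in {self.max_iter} alternations; "
                f"log-likelihood trace: {trace[-5:]}"
            )

        self.coef_ = params
        self.bse_ = np.asarray(res.bse)
        self.cov_params_ = np.asarray(res.cov_params())
        self.theta_ = theta
        self.loglik_ = ll
        self.n_ = len(y)
        self.k_ = len(params) + 1
        self.fitted_ = mu
        self.deviance_ = _nb_deviance(y, mu, theta)
        mu0 = np.full_like(y, y.mean())
        self.null_deviance_ = _nb_deviance(y, mu0, theta)
        self.converged_ = True
        self.random_intercept_ = None
        self.sigma_alpha2_ = None
        self.y_ = y
        return self

    def predict(self, X, return_se: bool = False, groups=None, mode: str = "population"):
        check_is_fitted(self, "coef_")
        design, names = _as_design(X)
        if names != self.term_names_:
            raise ValueError(f"design terms {names} do not match fit terms {self.term_names_}")
        eta = design @ self.coef_
        mu = np.exp(eta)
        if not return_se:
            return mu
        var_eta = np.einsum("ij,jk,ik->i", design, self.cov_params_, design)
        return mu, mu * np.sqrt(np.maximum(var_eta, 0.0))

    def to_json(self) -> str:
        check_is_fitted(self, "coef_")
        return json.dumps(
            {
                "terms": self.term_names_,
                "coef": self.coef_.tolist(),
                "bse": self.bse_.tolist(),
                "theta": self.theta_,
                "sigma_alpha2": self.sigma_alpha2_,
                "loglik": self.loglik_,
                "k": self.k_,
                "n": self.n_,
                "converged": self.converged_,
            },
            indent=2,
        )


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    """Name columns whose removal restores full rank (greedy scan)."""
    bad = []
    full = np.linalg.matrix_rank(design)
    for j in range(design.shape[1]):
        reduced = np.delete(design, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full:
            bad.append(names[j])
    return bad or names


class NegativeBinomialGLMM(RegressorMixin, BaseEstimator):
    """NB2 mixed model with one Gaussian random intercept per group.

    The random effects are integrated out with a Laplace approximation:
    for each candidate (beta, theta, sigma) the per-group intercept modes
    are found by a damped Newton iteration (the conditional log-density is
    concave in the intercept), and the marginal log-likelihood is the mode
    value plus the usual half-log-curvature correction.  The outer
    optimisation runs L-BFGS-B over (beta, log theta, log sigma).

    A boundary fit (sigma -> 0) is reported via ``boundary_`` rather than
    raised; there the Laplace log-likelihood collapses to the fixed-effects
    GLM log-likelihood.

    Standard errors for the coefficients come from the conditional Fisher
    information X'WX at the fitted modes (the uncertainty of theta and
    sigma is not propagated), matching common mixed-model practice.
    """

    #: sigma below this is treated as a boundary (sigma^2 ~ 0) fit
    BOUNDARY_SIGMA = 1e-4

    def __init__(self, tol: float = 1e-8, max_iter: int = 200,
                 sigma2_start: float = 0.1, theta_start: float | None = None):
        self.tol = tol
        self.max_iter = max_iter
        self.sigma2_start = sigma2_start
        self.theta_start = theta_start

    # -- Laplace machinery -------------------------------------------------

    @staticmethod
    def _modes(y, eta_fix, group_idx, n_groups, theta, sigma2, b0):
        """Vectorised per-group Newton for the conditional intercept modes."""
        b = b0.copy()
        for _ in range(60):
            mu = np.exp(eta_fix + b[group_idx])
            frac = mu / (theta + mu)
            grad = np.bincount(group_idx, weights=y - (y + theta) * frac,
                               minlength=n_groups) - b / sigma2
            curv = np.bincount(group_idx, weights=(y + theta) * theta * frac / (theta + mu),
                               minlength=n_groups) + 1.0 / sigma2
            step = grad / curv
            # Damp oversized steps; concavity makes plain Newton safe otherwise
            step = np.clip(step, -5.0, 5.0)
            b = b + step
            if np.max(np.abs(step)) < 1e-11:
                break
        return b

    def _neg_marginal(self, params, y, design, group_idx, n_groups, warm):
        p = design.shape[1]
        beta, log_theta, log_sigma = params[:p], params[p], params[p + 1]
        theta = np.exp(np.clip(log_theta, _MIN_LOG_THETA, _MAX_LOG_THETA))
        sigma2 = np.exp(2.0 * log_sigma)
        eta_fix = design @ beta
        if np.max(eta_fix) > 500:
            return 1e12
        b = self._modes(y, eta_fix, group_idx, n_groups, theta, sigma2, warm["b"])
        warm["b"] = b
        mu = np.exp(eta_fix + b[group_idx])
        ll_cond = nb2_loglik(y, mu, theta)
        frac = mu / (theta + mu)
        curv = np.bincount(group_idx, weights=(y + theta) * theta * frac / (theta + mu),
                           minlength=n_groups) + 1.0 / sigma2
        ll = (ll_cond
              - float(np.sum(b**2)) / (2.0 * sigma2)
              - 0.5 * n_groups * np.log(sigma2)
              - 0.5 * float(np.sum(np.log(curv))))
        return -ll

    # -- sklearn surface ---------------------------------------------------

    def fit(self, X, y, groups=None):
        if groups is None:
            raise ValueError("a grouping vector (reef ids) is required")
        y = _check_counts(y)
        design, names = _as_design(X)
        codes, levels = pd.factorize(np.asarray(groups))
        n_groups = len(levels)
        if n_groups < 2:
            raise ValueError("random intercept needs >= 2 groups")
        self.term_names_ = names
        self.group_levels_ = list(levels)

        glm = NegativeBinomialGLM(theta_start=self.theta_start).fit(X, y)
        theta0 = glm.theta_
        x0 = np.concatenate([glm.coef_,
                             [np.log(theta0), 0.5 * np.log(self.sigma2_start)]])
        warm = {"b": np.zeros(n_groups)}
        obj = lambda p: self._neg_marginal(p, y, design, codes, n_groups, warm)
        bounds = ([(None, None)] * design.shape[1]
                  + [(_MIN_LOG_THETA, _MAX_LOG_THETA), (np.log(1e-6), np.log(1e3))])
        res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": self.max_iter * 5,
                                         "ftol": self.tol, "gtol": 1e-7})
        if not res.success and res.status != 1:  # status 1 = maxiter
            raise RuntimeError(f"NB GLMM optimisation failed: {res.message}")

        p = design.shape[1]
        self.coef_ = res.x[:p]
        self.theta_ = float(np.exp(res.x[p]))
        sigma = float(np.exp(res.x[p + 1]))
        self.boundary_ = sigma < self.BOUNDARY_SIGMA
        self.sigma_alpha2_ = 0.0 if self.boundary_ else sigma**2
        self.loglik_ = -float(res.fun)
        self.n_ = len(y)
        self.k_ = p + 2  # coefficients + theta + sigma^2
        self.converged_ = bool(res.success)

        eta_fix = design @ self.coef_
        sigma2_eff = max(self.sigma_alpha2_, 1e-12)
        b = self._modes(y, eta_fix, codes, n_groups, self.theta_, sigma2_eff,
                        warm["b"] if not self.boundary_ else np.zeros(n_groups))
        if self.boundary_:
            b = np.zeros(n_groups)
        self.ranef_ = dict(zip(self.group_levels_, b))
        mu = np.exp(eta_fix + b[codes])
        self.fitted_ = mu
        w = (y + self.theta_) * self.theta_ * mu / (self.theta_ + mu) ** 2
        info = design.T @ (design * w[:, None])
        self.cov_params_ = np.linalg.pinv(info)
        self.bse_ = np.sqrt(np.diag(self.cov_params_))
        self.deviance_ = _nb_deviance(y, mu, self.theta_)
        self.null_deviance_ = _nb_deviance(y, np.full_like(y, y.mean()), self.theta_)
        self.random_intercept_ = "group"
        self.y_ = y
        self._codes_ = codes
        self._design_ = design
        return self

    def loglik_at_zero_variance(self, coef=None, theta: float | None = None,
                                sigma: float = 1e-8) -> float:
        """Laplace marginal log-likelihood with sigma pinned (numerically) to
        zero, at the given coefficients (default: this fit's).  In the limit
        this equals the fixed-effects GLM log-likelihood, since the modes
        collapse to zero and the curvature correction cancels the prior
        normalisation."""
        check_is_fitted(self, "coef_")
        coef = self.coef_ if coef is None else np.asarray(coef, dtype=float)
        theta = self.theta_ if theta is None else float(theta)
        params = np.concatenate([coef, [np.log(theta), np.log(sigma)]])
        warm = {"b": np.zeros(len(self.group_levels_))}
        return -self._neg_marginal(params, self.y_, self._design_, self._codes_,
                                   len(self.group_levels_), warm)

    def predict(self, X, groups=None, mode: str = "population", return_se: bool = False):
        """Expected counts on the response scale.

        ``population`` ignores the random effects (exp(X beta));
        ``conditional`` adds the conditional mode of each row's group when
        the group was seen in fitting, else falls back to population.
        """
        check_is_fitted(self, "coef_")
        design, names = _as_design(X)
        if names != self.term_names_:
            raise ValueError(f"design terms {names} do not match fit terms {self.term_names_}")
        eta = design @ self.coef_
        if mode == "conditional" and groups is not None:
            offsets = np.array([self.ranef_.get(g, 0.0) for g in np.asarray(groups)])
            eta = eta + offsets
        elif mode not in ("population", "conditional"):
            raise ValueError(f"unknown prediction mode {mode!r}")
        mu = np.exp(eta)
        if not return_se:
            return mu
        var_eta = np.einsum("ij,jk,ik->i", design, self.cov_params_, design)
        return mu, mu * np.sqrt(np.maximum(var_eta, 0.0))

    def to_json(self) -> str:
        check_is_fitted(self, "coef_")
        return json.dumps(
            {
                "terms": self.term_names_,
                "coef": self.coef_.tolist(),
                "bse": self.bse_.tolist(),
                "theta": self.theta_,
                "sigma_alpha2": self.sigma_alpha2_,
                "boundary": self.boundary_,
                "loglik": self.loglik_,
                "k": self.k_,
                "n": self.n_,
                "converged": self.converged_,
            },
            indent=2,
        )


def fit_poisson_glm(X, y):
    """Poisson GLM (log link) via statsmodels; used for the overdispersion check."""
    y = _check_counts(y)
    design, _ = _as_design(X)
    return sm.GLM(y, design, family=sm.families.Poisson()).fit()


def dispersion_statistic(poisson_fit) -> float:
    """Pearson dispersion: sum of squared Pearson residuals / residual df.

    Values near 1 indicate equidispersion; fish-count data typically give
    values far above 1, motivating the negative binomial.
    """
    resid = np.asarray(poisson_fit.resid_pearson)
    df = poisson_fit.df_resid
    if df <= 0:
        raise ValueError("dispersion statistic undefined for df_resid <= 0")
    return float(np.sum(resid**2) / df)
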