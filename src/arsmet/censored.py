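"""Left-censored log-normal (Tobit-type) regression.

Analyte concentrations below the limit of detection (LOD) are treated as
draws from the lower tail of a log-normal distribution whose location may
depend on covariates: on the log10 scale,

    log10(C_i) = x_i' beta + eps_i,   eps_i ~ N(0, sigma^2)

with detected samples contributing the normal density and non-detects the
normal CDF at their (log10) detection limit.  With no censoring the maximum
likelihood fit coincides with ordinary least squares on the log10 values.
Weighted likelihoods (survey weights) are supported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import ndtr, ndtri, log_ndtr
from sklearn.base import BaseEstimator

__all__ = [
    "EstimationError",
    "ConvergenceError",
    "CensoredFitParams",
    "CensoredLogNormalRegression",
    "fit_censored_lognormal",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class EstimationError(ValueError):
    """The censored fit is not identified (e.g. everything censored)."""


class ConvergenceError(RuntimeError):
    """Optimizer failed; carries the best point and iteration diagnostics."""

    def __init__(self, message, theta=None, n_iter=None):
        super().__init__(message)
        self.theta = theta
        self.n_iter = n_iter


@dataclass(frozen=True)
class CensoredFitParams:
    """Fitted left-censored log-normal regression on the log10 scale."""

    coefficients: np.ndarray
    residual_sd: float
    covariates: tuple[str, ...]
    cov_params: np.ndarray  # covariance of (coefficients, log residual_sd)
    loglik: float
    n_obs: int
    n_censored: int

    def __post_init__(self):
        if not self.residual_sd > 0:
            raise ValueError("residual SD must be positive")


class CensoredLogNormalRegression(BaseEstimator):
    """Maximum-likelihood left-censored normal regression of log10 values.

    Parameters
    ----------
    fit_intercept : prepend a constant column to the design.
    max_iter, tol : optimizer budget and gradient tolerance.

    Call :meth:`fit` with the concentrations on the original scale: censored
    rows carry their LOD in `y` and are flagged in `censored`.

    Attributes (after fit)
    ----------------------
    coef_ : regression coefficients on the log10 scale (intercept first when
        `fit_intercept`).
    sigma_ : residual SD on the log10 scale.
    cov_params_ : asymptotic covariance of (coef_, log sigma_) from the
        observed information.
    loglik_, converged_, n_iter_ : fit diagnostics.
    """

    def __init__(self, fit_intercept: bool = True, max_iter: int = 500, tol: float = 1e-10):
        self.fit_intercept = fit_intercept
        self.max_iter = max_iter
        self.tol = tol

    def _design(self, X, n):
        if X is None:
            x = np.empty((n, 0))
        else:
            x = np.atleast_2d(np.asarray(X, dtype=float))
            if x.shape[0] != n:
                x = x.T
        if self.fit_intercept:
            x = np.hstack([np.ones((n, 1)), x])
        if x.shape[1] == 0:
            raise ValueError("design has no columns; enable fit_intercept")
        return x

    def fit(self, X, y, censored=None, sample_weight=None):
        y = np.asarray(y, dtype=float)
        n = y.size
        if np.any(y <= 0):
            raise ValueError("concentrations (and LODs) must be positive")
        cens = (
            np.zeros(n, dtype=bool)
            if censored is None
            else np.asarray(censored, dtype=bool)
        )
        if cens.all():
            raise EstimationError("all values censored: location is not identified")
        w = (
            np.ones(n)
            if sample_weight is None
            else np.asarray(sample_weight, dtype=float)
        )
        if np.any(w <= 0):
            raise ValueError("sample weights must be positive")
        x = self._design(X, n)
        t = np.log10(y)  # observed log10 value, or log10 LOD when censored
        det = ~cens

        # start from (weighted) OLS on the observed values incl. LOD rows
        sw = np.sqrt(w)
        beta0, *_ = np.linalg.lstsq(x * sw[:, None], t * sw, rcond=None)
        resid0 = t - x @ beta0
        s0 = np.sqrt(np.average(resid0**2, weights=w))
        theta0 = np.concatenate([beta0, [np.log(max(s0, 1e-3))]])

        def negloglik_grad(theta):
            beta, log_s = theta[:-1], theta[-1]
            s = np.exp(log_s)
            mu = x @ beta
            z = (t - mu) / s
            ll = np.empty(n)
            ll[det] = -_LOG_SQRT_2PI - log_s - 0.5 * z[det] ** 2
            ll[cens] = log_ndtr(z[cens])
            nll = -float(w @ ll)

            # d ll / d mu and d ll / d log s per observation
            dmu = np.empty(n)
            dls = np.empty(n)
            dmu[det] = z[det] / s
            dls[det] = z[det] ** 2 - 1.0
            zc = z[cens]
            # phi(z)/Phi(z), computed stably via exp(log phi - log Phi)
            ratio = np.exp(-_LOG_SQRT_2PI - 0.5 * zc**2 - log_ndtr(zc))
            dmu[cens] = -ratio / s
            dls[cens] = -ratio * zc
            g_beta = -(x.T @ (w * dmu))
            g_ls = -float(w @ dls)
            return nll, np.concatenate([g_beta, [g_ls]])

        res = optimize.minimize(
            negloglik_grad,
            theta0,
            jac=True,
            method="BFGS",
            options={"maxiter": self.max_iter, "gtol": self.tol},
        )
        if not np.all(np.isfinite(res.x)):
            raise ConvergenceError(
                f"censored fit diverged after {res.nit} iterations: {res.message}",
                theta=res.x,
                n_iter=res.nit,
            )
        theta = res.x
        # observed information via central differences of the analytic gradient
        k = theta.size
        hess = np.empty((k, k))
        h = 1e-5 * np.maximum(1.0, np.abs(theta))
        for j in range(k):
            tp = theta.copy()
            tp[j] += h[j]
            tm = theta.copy()
            tm[j] -= h[j]
            gp = negloglik_grad(tp)[1]
            gm = negloglik_grad(tm)[1]
            hess[:, j] = (gp - gm) / (2.0 * h[j])
        hess = 0.5 * (hess + hess.T)
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(hess)

        self.coef_ = theta[:-1]
        self.sigma_ = float(np.exp(theta[-1]))
        self.cov_params_ = cov
        self.loglik_ = -float(res.fun)
        self.converged_ = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-4
        self.n_iter_ = int(res.nit)
        self.n_obs_ = n
        self.n_censored_ = int(cens.sum())
        if not self.converged_:
            raise ConvergenceError(
                f"censored fit did not converge in {res.nit} iterations "
                f"(|grad|={np.max(np.abs(res.jac)):.2e}): {res.message}",
                theta=theta,
                n_iter=res.nit,
            )
        return self

    def predict(self, X) -> np.ndarray:
        """Conditional mean of log10 concentration."""
        if not hasattr(self, "coef_"):
            raise AttributeError("model is not fitted")
        n = np.atleast_2d(np.asarray(X, dtype=float)).shape[0] if X is not None else 1
        x = self._design(X, n)
        return x @ self.coef_

    def sample_params(self, rng: np.random.Generator):
        """Draw (coefficients, sigma) from their asymptotic distribution.

        Used for proper multiple imputation: each completed dataset is
        generated under its own parameter draw so between-imputation variance
        reflects estimation uncertainty.
        """
        theta = np.concatenate([self.coef_, [np.log(self.sigma_)]])
        cov = self.cov_params_
        # guard tiny negative eigenvalues from the numeric Hessian
        evals, evecs = np.linalg.eigh(cov)
        root = evecs * np.sqrt(np.clip(evals, 0.0, None))
        draw = theta + root @ rng.standard_normal(theta.size)
        return draw[:-1], float(np.exp(draw[-1]))


def fit_censored_lognormal(
    values,
    censored,
    covariates=None,
    covariate_names: tuple[str, ...] = (),
    sample_weight=None,
) -> CensoredFitParams:
    """Functional wrapper: fit the left-censored log-normal model.

    Parameters
    ----------
    values : concentrations on the original scale; censored entries carry
        their LOD.
    censored : boolean flags marking non-detects.
    covariates : optional (n, p) design (an intercept is always added).

    Returns a :class:`CensoredFitParams` with coefficients on the log10 scale.
    """
    values = np.asarray(values, dtype=float)
    cens = np.asarray(censored, dtype=bool)
    if not (~cens).any():
        raise EstimationError("need at least one detected value")
    est = CensoredLogNormalRegression()
    est.fit(covariates, values, censored=cens, sample_weight=sample_weight)
    names = ("intercept",) + tuple(covariate_names)
    return CensoredFitParams(
        coefficients=est.coef_,
        residual_sd=est.sigma_,
        covariates=names,
        cov_params=est.cov_params_,
        loglik=est.loglik_,
        n_obs=est.n_obs_,
        n_censored=est.n_censored_,
    )


def truncated_normal_draw(rng, mu, sigma, upper):
    """Draw from N(mu, sigma^2) truncated above at `upper` via inverse CDF."""
    mu = np.asarray(mu, dtype=float)
    upper = np.asarray(upper, dtype=float)
    p_upper = ndtr((upper - mu) / sigma)
    # keep strictly inside (0, p_upper) so draws stay strictly below `upper`
    u = rng.uniform(0.0, 1.0, size=np.broadcast(mu, upper).shape)
    q = np.clip(u * p_upper, 1e-12, 1.0 - 1e-12)
    return mu + sigma * ndtri(q)
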