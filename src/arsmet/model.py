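"""Non-linear offset dose-response model for urinary arsenic biomarkers.

The final multivariate model predicts a transformed biomarker Y (log10 of a
urinary concentration or index, or logit of a relative level) from home
tap-water arsenic and covariates::

    Y = a_DWS + b_DWS * log10(10**a_LogOffset + WaterAs)
        + b_Q * log10(tap water consumption) + b_C * log10(creatinine)
        + b_F * female + b_B * log10(BMI) + b_A * log10(age)
        + b_S * log10(cotinine) + b_R * recent_fish

with a separate intercept a_DWS and slope b_DWS for each of the four
drinking-water-source categories (untreated tap, filtered tap, other
treatment, bottled).  The positive water-arsenic offset 10**a_LogOffset keeps
the dose term finite and monotone at zero water arsenic and can be read as
unmeasured background arsenic intake; it is estimated on the log10 scale to
keep it positive.  For the relative-level and methylation-index outcomes the
offset is dropped and the dose term is plain log10(WaterAs).

For a fixed offset the model is linear in every other coefficient, so the
fit profiles the offset: an inner linear least squares solves for the linear
coefficients at each candidate offset, an outer 1-d minimisation (seeded by a
multi-start grid) finds the offset, and a final damped Gauss-Newton polish on
the full parameter vector supplies the Jacobian used for the asymptotic
covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .derived import recode_water_consumption

__all__ = [
    "WATER_SOURCES",
    "ModelParameters",
    "FitResult",
    "transform_water_as",
    "OffsetDoseResponseModel",
    "fit_offset_model",
    "predict_response",
    "significance_stars",
]

WATER_SOURCES = ("untreated", "filtered", "other_treatment", "bottled")

#: covariate columns entering linearly, in design order
_COVARIATES = (
    "log10_consumption",
    "log10_creatinine",
    "female",
    "log10_bmi",
    "log10_age",
    "log10_cotinine",
    "recent_fish",
)


@dataclass(frozen=True)
class ModelParameters:
    """Full coefficient set of the dose-response model.

    `alpha` / `beta` map each water source to its intercept / slope.  When
    `offset_enabled` is False the water term is plain log10(WaterAs) and
    `alpha_log_offset` is ignored.
    """

    alpha: Mapping[str, float]
    beta: Mapping[str, float]
    alpha_log_offset: float
    beta_consumption: float
    beta_creatinine: float
    beta_female: float
    beta_bmi: float
    beta_age: float
    beta_cotinine: float
    beta_fish: float
    offset_enabled: bool = True

    def __post_init__(self):
        for src in WATER_SOURCES:
            if src not in self.alpha or src not in self.beta:
                raise ValueError(f"missing intercept/slope for source {src!r}")

    @property
    def beta_offset(self) -> float:
        """The water-arsenic offset on the concentration scale (ug/L)."""
        return 10.0 ** self.alpha_log_offset

    def to_vector(self) -> np.ndarray:
        v = [self.alpha[s] for s in WATER_SOURCES]
        v += [self.beta[s] for s in WATER_SOURCES]
        if self.offset_enabled:
            v.append(self.alpha_log_offset)
        v += [
            self.beta_consumption,
            self.beta_creatinine,
            self.beta_female,
            self.beta_bmi,
            self.beta_age,
            self.beta_cotinine,
            self.beta_fish,
        ]
        return np.array(v, dtype=float)

    @classmethod
    def from_vector(cls, v: np.ndarray, offset_enabled: bool = True) -> "ModelParameters":
        v = np.asarray(v, dtype=float)
        n_expected = 8 + (1 if offset_enabled else 0) + 7
        if v.size != n_expected:
            raise ValueError(f"expected {n_expected} parameters, got {v.size}")
        alpha = dict(zip(WATER_SOURCES, v[:4]))
        beta = dict(zip(WATER_SOURCES, v[4:8]))
        k = 8
        if offset_enabled:
            alo = float(v[8])
            k = 9
        else:
            alo = float("nan")
        return cls(
            alpha=alpha,
            beta=beta,
            alpha_log_offset=alo,
            beta_consumption=float(v[k]),
            beta_creatinine=float(v[k + 1]),
            beta_female=float(v[k + 2]),
            beta_bmi=float(v[k + 3]),
            beta_age=float(v[k + 4]),
            beta_cotinine=float(v[k + 5]),
            beta_fish=float(v[k + 6]),
            offset_enabled=offset_enabled,
        )

    def parameter_names(self) -> list[str]:
        names = [f"intercept_{s}" for s in WATER_SOURCES]
        names += [f"slope_{s}" for s in WATER_SOURCES]
        if self.offset_enabled:
            names.append("alpha_log_offset")
        names += list(_COVARIATES)
        return names


def parameter_names(offset_enabled: bool = True) -> list[str]:
    names = [f"intercept_{s}" for s in WATER_SOURCES]
    names += [f"slope_{s}" for s in WATER_SOURCES]
    if offset_enabled:
        names.append("alpha_log_offset")
    names += list(_COVARIATES)
    return names


def transform_water_as(water_as, alpha_log_offset: float):
    """Offset-log dose transform: log10(10**alpha_log_offset + water_as).

    Strictly increasing in `water_as` and finite at zero; large offsets
    flatten the low-dose end of the curve.
    """
    w = np.asarray(water_as, dtype=float)
    if np.any(w < 0):
        raise ValueError("water arsenic concentrations must be >= 0")
    out = np.log10(10.0 ** alpha_log_offset + w)
    return float(out) if out.ndim == 0 else out


def significance_stars(p: float) -> str:
    """Report-style significance bins: *** P<0.0001, ** P<0.001, * P<0.05."""
    if math.isnan(p):
        return ""
    if p < 0.0001:
        return "***"
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _design_components(frame: pd.DataFrame):
    """Source indicator matrix S (n,4), water vector, covariate matrix Z."""
    src = frame["water_source"].astype(str).to_numpy()
    unknown = set(src) - set(WATER_SOURCES)
    if unknown:
        raise ValueError(f"unknown water source categories: {sorted(unknown)}")
    s_mat = np.column_stack([(src == s).astype(float) for s in WATER_SOURCES])
    water = frame["water_tas"].to_numpy(dtype=float)

    cols = {}
    if "log10_consumption" in frame:
        cols["log10_consumption"] = frame["log10_consumption"].to_numpy(dtype=float)
    else:
        cols["log10_consumption"] = np.log10(
            recode_water_consumption(
                frame["tap_water_consumption"].to_numpy(dtype=float)
            )
        )
    for name, raw in (
        ("log10_creatinine", "creatinine"),
        ("log10_bmi", "bmi"),
        ("log10_age", "age"),
        ("log10_cotinine", "cotinine"),
    ):
        if name in frame:
            cols[name] = frame[name].to_numpy(dtype=float)
        else:
            cols[name] = np.log10(frame[raw].to_numpy(dtype=float))
    if "female" in frame:
        cols["female"] = frame["female"].to_numpy(dtype=float)
    else:
        cols["female"] = (frame["gender"].astype(str) == "female").to_numpy(dtype=float)
    cols["recent_fish"] = frame["recent_fish"].to_numpy(dtype=float)
    z = np.column_stack([cols[c] for c in _COVARIATES])
    return s_mat, water, z


def _linear_design(s_mat, dose, z):
    return np.hstack([s_mat, s_mat * dose[:, None], z])


@dataclass(frozen=True)
class FitResult:
    """One model fit on one completed dataset."""

    dependent: str
    imputation: int
    params: ModelParameters
    estimates: np.ndarray
    cov: np.ndarray
    residual_sd: float
    sse: float
    n_obs: int
    converged: bool
    n_iter: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def table(self) -> pd.DataFrame:
        names = self.params.parameter_names()
        se = self.se
        dof = self.n_obs - len(names)
        t = np.divide(self.estimates, se, out=np.full_like(se, np.nan), where=se > 0)
        p = 2.0 * stats.t.sf(np.abs(t), dof)
        return pd.DataFrame(
            {
                "parameter": names,
                "estimate": self.estimates,
                "se": se,
                "t": t,
                "p_value": p,
                "stars": [significance_stars(v) for v in p],
            }
        )


class OffsetDoseResponseModel(RegressorMixin, BaseEstimator):
    """Dose-response regression with per-source intercepts/slopes and an
    estimated water-arsenic offset.

    Parameters
    ----------
    dependent : name of the response column used when `y` is not passed to
        :meth:`fit`.
    offset_enabled : estimate the log10 water offset (absolute-concentration
        outcomes); when False the water term is plain log10(WaterAs) and the
        model is linear (relative levels, methylation indices).
    offset_starts : multi-start grid for the log10 offset.
    offset_bounds : search interval for the log10 offset.
    tol : relative SSE / gradient convergence tolerance of the final polish.

    Attributes (after fit)
    ----------------------
    params_ : ModelParameters with the fitted coefficients.
    estimates_, cov_, se_ : coefficient vector, Gauss-Newton covariance, SEs.
    sigma_ : residual standard deviation.
    param_names_ : coefficient names matching `estimates_`.
    converged_, n_iter_ : convergence diagnostics.
    """

    def __init__(
        self,
        dependent: str = "log10_usas",
        offset_enabled: bool = True,
        offset_starts: Sequence[float] = (-1.0, 0.0, 0.5, 1.0, 1.5),
        offset_bounds: tuple[float, float] = (-3.0, 3.5),
        tol: float = 1e-10,
        max_iter: int = 200,
    ):
        self.dependent = dependent
        self.offset_enabled = offset_enabled
        self.offset_starts = offset_starts
        self.offset_bounds = offset_bounds
        self.tol = tol
        self.max_iter = max_iter

    # -- internals -----------------------------------------------------
    @staticmethod
    def _profile_sse(a, s_mat, water, z, y):
        dose = np.log10(10.0 ** a + water)
        x = _linear_design(s_mat, dose, z)
        coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ coef
        return float(resid @ resid), coef

    def fit(self, X: pd.DataFrame, y=None):
        frame = X
        if y is None:
            if self.dependent not in frame:
                raise ValueError(
                    f"response column {self.dependent!r} not in the dataset; "
                    "pass y explicitly or derive the column first"
                )
            y = frame[self.dependent].to_numpy(dtype=float)
        else:
            y = np.asarray(y, dtype=float)
        s_mat, water, z = _design_components(frame)
        n = y.size
        if np.any(~np.isfinite(y)):
            raise ValueError("response contains non-finite values")

        if not self.offset_enabled:
            if np.any(water <= 0):
                raise ValueError(
                    "offset-free model needs strictly positive water arsenic "
                    "(completed data)"
                )
            dose = np.log10(water)
            x = _linear_design(s_mat, dose, z)
            coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
            resid = y - x @ coef
            sse = float(resid @ resid)
            dof = n - x.shape[1]
            sigma2 = sse / dof
            cov = sigma2 * np.linalg.pinv(x.T @ x)
            self._finalize(frame, coef, cov, sse, n, True, 1)
            return self

        # profile the log-offset: grid multi-start then 1-d refinement
        lo, hi = self.offset_bounds
        starts = sorted(set(float(a) for a in self.offset_starts))
        grid = np.unique(np.clip(np.concatenate(
            [np.asarray(starts), np.linspace(lo, hi, 19)]), lo, hi))
        sse_grid = [self._profile_sse(a, s_mat, water, z, y)[0] for a in grid]
        i_best = int(np.argmin(sse_grid))
        a_lo = grid[max(i_best - 1, 0)]
        a_hi = grid[min(i_best + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda a: self._profile_sse(a, s_mat, water, z, y)[0],
            bounds=(a_lo, a_hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        a_opt = float(res.x)
        sse_opt, coef_lin = self._profile_sse(a_opt, s_mat, water, z, y)

        # full-vector Gauss-Newton polish with analytic Jacobian
        theta0 = np.concatenate([coef_lin[:8], [a_opt], coef_lin[8:]])

        def residuals(theta):
            return y - _evaluate(theta, s_mat, water, z, True)

        def jac(theta):
            return -_jacobian(theta, s_mat, water, z)

        ls = optimize.least_squares(
            residuals,
            theta0,
            jac=jac,
            method="lm",
            xtol=self.tol,
            ftol=self.tol,
            gtol=1e-12,
            max_nfev=self.max_iter * theta0.size,
        )
        sse = float(2.0 * ls.cost)
        if sse > sse_opt + 1e-9 * (1.0 + sse_opt):  # keep the better solution
            theta = theta0
            sse = sse_opt
            j = -jac(theta0)
        else:
            theta = ls.x
            j = -ls.jac
        dof = n - theta.size
        if dof <= 0:
            raise ValueError("more parameters than observations")
        sigma2 = sse / dof
        cov = sigma2 * np.linalg.pinv(j.T @ j)
        self._finalize(frame, theta, cov, sse, n, bool(ls.success), int(ls.nfev))
        return self

    def _finalize(self, frame, theta, cov, sse, n, converged, n_iter):
        self.params_ = ModelParameters.from_vector(theta, self.offset_enabled)
        self.estimates_ = np.asarray(theta, dtype=float)
        self.cov_ = cov
        self.se_ = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        self.sse_ = sse
        self.n_obs_ = n
        self.sigma_ = math.sqrt(sse / max(n - theta.size, 1))
        self.param_names_ = self.params_.parameter_names()
        self.converged_ = converged
        self.n_iter_ = n_iter

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise AttributeError("model is not fitted")
        return predict_response(self.params_, X)

    def result(self, dependent: str | None = None, imputation: int = 0) -> FitResult:
        return FitResult(
            dependent=dependent or self.dependent,
            imputation=imputation,
            params=self.params_,
            estimates=self.estimates_,
            cov=self.cov_,
            residual_sd=self.sigma_,
            sse=self.sse_,
            n_obs=self.n_obs_,
            converged=self.converged_,
            n_iter=self.n_iter_,
        )


def _evaluate(theta, s_mat, water, z, offset_enabled):
    theta = np.asarray(theta, dtype=float)
    alpha = theta[:4]
    beta = theta[4:8]
    if offset_enabled:
        a = theta[8]
        gamma = theta[9:]
        dose = np.log10(10.0 ** a + water)
    else:
        gamma = theta[8:]
        dose = np.log10(water)
    return s_mat @ alpha + (s_mat @ beta) * dose + z @ gamma


def _jacobian(theta, s_mat, water, z):
    """d model / d theta for the offset-enabled parameterisation."""
    a = theta[8]
    beta = theta[4:8]
    pow_a = 10.0 ** a
    dose = np.log10(pow_a + water)
    d_dose_da = pow_a / (pow_a + water)
    cols = [s_mat, s_mat * dose[:, None],
            ((s_mat @ beta) * d_dose_da)[:, None], z]
    return np.hstack(cols)


def fit_offset_model(
    dataset: pd.DataFrame,
    dependent: str,
    offset_enabled: bool = True,
    imputation: int = 0,
    **kwargs,
) -> FitResult:
    """Fit the dose-response model to one completed dataset.

    Thin functional wrapper around :class:`OffsetDoseResponseModel`.
    """
    est = OffsetDoseResponseModel(
        dependent=dependent, offset_enabled=offset_enabled, **kwargs
    )
    est.fit(dataset)
    return est.result(dependent=dependent, imputation=imputation)


def predict_response(params: ModelParameters, covariates: pd.DataFrame) -> np.ndarray:
    """Evaluate the model equation at given covariates.

    `covariates` is a cohort-style frame (raw or derived columns); returns the
    predicted transformed response (log10 or logit scale).
    """
    s_mat, water, z = _design_components(covariates)
    theta = params.to_vector()
    return _evaluate(theta, s_mat, water, z, params.offset_enabled)
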