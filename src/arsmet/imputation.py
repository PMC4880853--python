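"""Multiple imputation of non-detects and missing values.

Below-LOD analyte cells are filled with draws from the lower tail of a
fitted conditional log-normal distribution (left-censored regression on
log10 concentrations, see :mod:`arsmet.censored`); missing covariate cells
are filled from fitted log-normal models.  The procedure is *proper*: before
each completed dataset is generated, the model parameters themselves are
drawn from their asymptotic distribution, so the spread across the M
datasets reflects estimation uncertainty as well as residual noise.

Conditional structure (a documented design choice; the source analysis states
only that imputation maintained correlations among analysis variables):

1. water arsenic non-detects - intercept-only censored log-normal;
2. missing covariates (BMI, cotinine, creatinine) - log-normal draws;
3. urinary species and toenail arsenic in the fixed order
   DMA -> MMA -> iAs(III) -> iAs(V) -> nails, each regressed on log10 water
   (completed), gender, log10 age, log10 BMI, water-source indicators,
   log10 creatinine, and the log10 of the already-completed analytes earlier
   in the order.  Censored cells are drawn from the conditional normal
   truncated above at the log10 LOD (inverse-CDF), so every imputed
   non-detect lies strictly inside (0, LOD); missing cells (nails) are drawn
   untruncated.

The default M = 20 completed datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .censored import (
    CensoredLogNormalRegression,
    EstimationError,
    truncated_normal_draw,
)
from .model import WATER_SOURCES

__all__ = ["ImputedDataset", "CohortImputer", "impute_nondetects"]

ANALYTE_ORDER = ("dma", "mma", "ias3", "ias5", "nail_tas")
_LOGNORMAL_COVARIATES = ("bmi", "cotinine", "creatinine")


@dataclass
class ImputedDataset:
    """One completed copy of the cohort.

    `frame` has every non-detect and missing cell filled (all `*_nd` flags
    cleared); `provenance` is a boolean mask over the imputed columns marking
    which cells were filled.
    """

    m: int
    frame: pd.DataFrame
    provenance: pd.DataFrame


def _base_design(df: pd.DataFrame, water: np.ndarray):
    cols = [
        np.log10(water),
        (df["gender"].astype(str) == "female").to_numpy(float),
        np.log10(df["age"].to_numpy(float)),
        np.log10(df["bmi"].to_numpy(float)),
        np.log10(df["creatinine"].to_numpy(float)),
    ]
    names = ["log10_water", "female", "log10_age", "log10_bmi", "log10_creatinine"]
    src = df["water_source"].astype(str).to_numpy()
    for s in WATER_SOURCES[1:]:  # untreated is the reference
        cols.append((src == s).astype(float))
        names.append(f"source_{s}")
    return np.column_stack(cols), names


class CohortImputer(BaseEstimator):
    """Proper multiple imputation of a censored cohort table.

    Parameters
    ----------
    m : number of completed datasets to create (default 20).
    random_state : seed for the imputation draws.
    proper : draw model parameters from their asymptotic distribution before
        each imputation (set False for a fixed-parameter, improper variant
        used in debugging).

    After :meth:`fit`, `water_model_`, `covariate_models_` and
    `analyte_models_` hold the fitted conditional models;
    :meth:`transform` produces the list of :class:`ImputedDataset`.
    """

    def __init__(self, m: int = 20, random_state=None, proper: bool = True):
        self.m = m
        self.random_state = random_state
        self.proper = proper

    # ------------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None):
        if self.m < 2:
            raise ValueError("m must be >= 2 for multiple imputation")
        df = X
        # water: intercept-only censored log-normal
        wm = CensoredLogNormalRegression()
        wm.fit(None, df["water_tas"].to_numpy(float),
               censored=df["water_tas_nd"].to_numpy(bool))
        self.water_model_ = wm

        # covariates with missing cells: intercept-only normal on log10
        self.covariate_models_ = {}
        for col in _LOGNORMAL_COVARIATES:
            vals = df[col].to_numpy(float)
            obs = np.log10(vals[np.isfinite(vals)])
            n = obs.size
            if n < 2:
                raise EstimationError(f"too few observed values for {col!r}")
            self.covariate_models_[col] = {
                "mean": float(obs.mean()),
                "sd": float(obs.std(ddof=1)),
                "n": n,
            }

        # analytes: censored regressions fitted on rows with complete
        # covariates, predecessors entering at their observed-or-LOD value
        complete = np.ones(len(df), dtype=bool)
        for col in ("bmi", "cotinine", "creatinine"):
            complete &= np.isfinite(df[col].to_numpy(float))
        water_fit = df["water_tas"].to_numpy(float)
        self.analyte_models_ = {}
        prior_cols = []
        for analyte in ANALYTE_ORDER:
            vals = df[analyte].to_numpy(float)
            nd = df[f"{analyte}_nd"].to_numpy(bool)
            rows = complete & np.isfinite(vals)
            design_prior = [
                np.log10(df.loc[rows, p].to_numpy(float)) for p in prior_cols
            ]
            base_r, _ = _base_design(df[rows], water_fit[rows])
            design = (
                np.hstack([base_r] + [c[:, None] for c in design_prior])
                if design_prior
                else base_r
            )
            if nd[rows].all():
                raise EstimationError(f"all {analyte!r} values are censored")
            est = CensoredLogNormalRegression()
            est.fit(design, vals[rows], censored=nd[rows])
            self.analyte_models_[analyte] = est
            prior_cols.append(analyte)
        self.columns_ = list(X.columns)
        return self

    # ------------------------------------------------------------------
    def _draw(self, model: CensoredLogNormalRegression, rng):
        if self.proper:
            return model.sample_params(rng)
        return model.coef_, model.sigma_

    def _impute_once(self, df: pd.DataFrame, m_index: int, rng) -> ImputedDataset:
        out = df.copy()
        prov = {}

        # water arsenic
        wnd = out["water_tas_nd"].to_numpy(bool)
        prov["water_tas"] = wnd.copy()
        if wnd.any():
            coef, sigma = self._draw(self.water_model_, rng)
            mu = np.full(int(wnd.sum()), coef[0])
            upper = np.log10(out.loc[wnd, "water_tas"].to_numpy(float))
            draws = truncated_normal_draw(rng, mu, sigma, upper)
            out.loc[wnd, "water_tas"] = 10.0 ** draws
        out["water_tas_nd"] = False

        # missing covariates
        for col, fitpars in self.covariate_models_.items():
            vals = out[col].to_numpy(float)
            miss = ~np.isfinite(vals)
            prov[col] = miss.copy()
            if miss.any():
                if self.proper:
                    n = fitpars["n"]
                    chi2 = rng.chisquare(n - 1)
                    sd = fitpars["sd"] * np.sqrt((n - 1) / chi2)
                    mean = fitpars["mean"] + sd / np.sqrt(n) * rng.standard_normal()
                else:
                    mean, sd = fitpars["mean"], fitpars["sd"]
                out.loc[miss, col] = 10.0 ** rng.normal(
                    mean, sd, size=int(miss.sum())
                )

        # analytes, sequentially on completed predecessors
        water_full = out["water_tas"].to_numpy(float)
        base, _ = _base_design(out, water_full)
        prior_cols = []
        for analyte in ANALYTE_ORDER:
            model = self.analyte_models_[analyte]
            vals = out[analyte].to_numpy(float)
            nd = out[f"{analyte}_nd"].to_numpy(bool)
            miss = ~np.isfinite(vals)
            prov[analyte] = nd | miss
            design_prior = [
                np.log10(out[p].to_numpy(float))[:, None] for p in prior_cols
            ]
            design = np.hstack([base] + design_prior) if design_prior else base
            design = np.hstack([np.ones((len(out), 1)), design])
            coef, sigma = self._draw(model, rng)
            mu = design @ coef
            if nd.any():
                upper = np.log10(vals[nd])
                draws = truncated_normal_draw(rng, mu[nd], sigma, upper)
                vals = vals.copy()
                vals[nd] = 10.0 ** draws
            if miss.any():
                vals = vals.copy()
                vals[miss] = 10.0 ** rng.normal(mu[miss], sigma)
            out[analyte] = vals
            out[f"{analyte}_nd"] = False
            prior_cols.append(analyte)

        return ImputedDataset(
            m=m_index, frame=out, provenance=pd.DataFrame(prov, index=df.index)
        )

    def transform(self, X: pd.DataFrame) -> list[ImputedDataset]:
        if not hasattr(self, "analyte_models_"):
            raise AttributeError("imputer is not fitted")
        seeds = np.random.SeedSequence(self.random_state).spawn(self.m)
        return [
            self._impute_once(X, i + 1, np.random.default_rng(seeds[i]))
            for i in range(self.m)
        ]

    def fit_transform(self, X: pd.DataFrame, y=None) -> list[ImputedDataset]:
        return self.fit(X).transform(X)


def impute_nondetects(
    cohort: pd.DataFrame, m: int = 20, seed=None, proper: bool = True
) -> list[ImputedDataset]:
    """Fit the conditional models and produce M completed datasets."""
    return CohortImputer(m=m, random_state=seed, proper=proper).fit_transform(cohort)
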