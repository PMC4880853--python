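"""Derived analysis variables for urinary arsenic speciation.

From the four measured urinary species (arsenite iAs(III), arsenate iAs(V),
monomethylarsonic acid MMA, dimethylarsinic acid DMA) the analysis works with

* TiAs  = iAs(III) + iAs(V), total inorganic arsenic;
* USAs  = TiAs + MMA + DMA, total speciated arsenic (denominator of the
  relative levels %TiAs, %MMA, %DMA);
* PMI   = MMA / TiAs, the primary methylation index;
* SMI   = DMA / MMA, the secondary methylation index,

plus log10 transforms of the concentration-scale variables and logit
transforms of the percentages.  Concentrations are in ug/L and are never
creatinine- or specific-gravity-corrected; creatinine enters the regression
model only as a covariate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DerivedVariables",
    "compute_derived",
    "logit_percent",
    "inverse_logit_percent",
    "recode_water_consumption",
    "smoking_category",
    "cigarette_exposure_fraction",
    "add_derived_columns",
    "DEPENDENT_VARIABLES",
]

#: The nine dependent variables modelled downstream, as column names produced
#: by :func:`add_derived_columns`.
DEPENDENT_VARIABLES = (
    "log10_tias",
    "log10_mma",
    "log10_dma",
    "log10_usas",
    "logit_pct_tias",
    "logit_pct_mma",
    "logit_pct_dma",
    "log10_pmi",
    "log10_smi",
)

#: Clipping bounds (in percent) applied before the logit transform so that
#: completed datasets with extreme compositions stay finite.
LOGIT_CLIP_PCT = (0.1, 99.9)


@dataclass(frozen=True)
class DerivedVariables:
    tias: float
    usas: float
    pct_tias: float
    pct_mma: float
    pct_dma: float
    pmi: float
    smi: float
    log10_tias: float
    log10_mma: float
    log10_dma: float
    log10_usas: float
    log10_pmi: float
    log10_smi: float
    logit_pct_tias: float
    logit_pct_mma: float
    logit_pct_dma: float


def compute_derived(ias3: float, ias5: float, mma: float, dma: float) -> DerivedVariables:
    """Derive summed species, relative levels and methylation indices.

    All four inputs must be strictly positive (completed data only).
    """
    for name, v in (("ias3", ias3), ("ias5", ias5), ("mma", mma), ("dma", dma)):
        if not v > 0:
            raise ValueError(f"{name} must be > 0 on completed data, got {v!r}")
    tias = ias3 + ias5
    usas = tias + mma + dma
    pct_tias = 100.0 * tias / usas
    pct_mma = 100.0 * mma / usas
    pct_dma = 100.0 * dma / usas
    pmi = mma / tias
    smi = dma / mma
    return DerivedVariables(
        tias=tias,
        usas=usas,
        pct_tias=pct_tias,
        pct_mma=pct_mma,
        pct_dma=pct_dma,
        pmi=pmi,
        smi=smi,
        log10_tias=math.log10(tias),
        log10_mma=math.log10(mma),
        log10_dma=math.log10(dma),
        log10_usas=math.log10(usas),
        log10_pmi=math.log10(pmi),
        log10_smi=math.log10(smi),
        logit_pct_tias=logit_percent(pct_tias),
        logit_pct_mma=logit_percent(pct_mma),
        logit_pct_dma=logit_percent(pct_dma),
    )


def logit_percent(p, clip=LOGIT_CLIP_PCT):
    """Logit of a percentage: ln((p/100) / (1 - p/100)).

    Percentages are clipped into `clip` (default [0.1, 99.9]) first so the
    transform stays finite on degenerate compositions.
    """
    p = np.clip(np.asarray(p, dtype=float), clip[0], clip[1])
    f = p / 100.0
    out = np.log(f / (1.0 - f))
    return float(out) if out.ndim == 0 else out


def inverse_logit_percent(x):
    """Inverse of :func:`logit_percent` (without the clip)."""
    x = np.asarray(x, dtype=float)
    out = 100.0 / (1.0 + np.exp(-x))
    return float(out) if out.ndim == 0 else out


def recode_water_consumption(liters):
    """Recode zero reported tap-water consumption to 0.06 L/day (a quarter
    cup) so the variable can be log-transformed; positive values pass through.
    """
    arr = np.asarray(liters, dtype=float)
    if np.any(arr < 0):
        raise ValueError("tap-water consumption cannot be negative")
    out = np.where(arr == 0.0, 0.06, arr)
    return float(out) if out.ndim == 0 else out


def smoking_category(cotinine, creatinine, cutoff_ng_per_mg: float = 100.0):
    """Classify smoking status from creatinine-corrected urinary cotinine.

    Parameters
    ----------
    cotinine : urinary cotinine, ug/L (== ng/mL).
    creatinine : urinary creatinine, mg/dL.
    cutoff_ng_per_mg : corrected-cotinine threshold in ng cotinine per mg
        creatinine; at or above → smoker.

    Returns ``1`` (smoker) / ``0`` (non-smoker), vectorised.
    """
    cot = np.asarray(cotinine, dtype=float)
    cre = np.asarray(creatinine, dtype=float)
    if np.any(cre <= 0):
        raise ValueError("creatinine must be > 0 for cotinine correction")
    # ng/mL divided by mg/mL of creatinine: mg/dL -> mg/mL is /100
    corrected = cot / (cre / 100.0)
    out = (corrected >= cutoff_ng_per_mg).astype(int)
    return int(out) if out.ndim == 0 else out


def cigarette_exposure_fraction(
    cigs_per_day: float,
    as_per_cig_ug: float,
    water_liters: float,
    water_conc_ug_per_l: float,
) -> tuple[float, float]:
    """Aggregate-exposure arithmetic for arsenic inhaled from cigarettes.

    Returns ``(daily_smoking_as, fraction_pct)``: the daily arsenic dose from
    smoking (ug/day, reported at 2 decimals) and its share of total daily
    arsenic intake including drinking water (percent, reported at 1 decimal).
    """
    for name, v in (
        ("cigs_per_day", cigs_per_day),
        ("as_per_cig_ug", as_per_cig_ug),
        ("water_liters", water_liters),
        ("water_conc_ug_per_l", water_conc_ug_per_l),
    ):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v!r}")
    smoking_as = cigs_per_day * as_per_cig_ug
    water_as = water_liters * water_conc_ug_per_l
    total = smoking_as + water_as
    if total <= 0:
        raise ValueError("total daily arsenic intake is zero")
    fraction = 100.0 * smoking_as / total
    return round(smoking_as, 2), round(fraction, 1)


def add_derived_columns(frame: pd.DataFrame) -> pd.DataFrame:
    """Augment a completed cohort table with all derived analysis columns.

    Expects completed (strictly positive) `ias3`, `ias5`, `mma`, `dma`
    columns plus the covariates; adds summed species, percentages,
    methylation indices, their transforms, the recoded/log water-consumption
    column and log10 transforms of the continuous predictors.
    """
    df = frame.copy()
    species = df[["ias3", "ias5", "mma", "dma"]].to_numpy(dtype=float)
    if np.any(species <= 0):
        raise ValueError("species columns must be completed (strictly > 0)")
    df["tias"] = df["ias3"] + df["ias5"]
    df["usas"] = df["tias"] + df["mma"] + df["dma"]
    df["pct_tias"] = 100.0 * df["tias"] / df["usas"]
    df["pct_mma"] = 100.0 * df["mma"] / df["usas"]
    df["pct_dma"] = 100.0 * df["dma"] / df["usas"]
    df["pmi"] = df["mma"] / df["tias"]
    df["smi"] = df["dma"] / df["mma"]
    for col in ("tias", "mma", "dma", "usas", "pmi", "smi"):
        df[f"log10_{col}"] = np.log10(df[col])
    for col in ("pct_tias", "pct_mma", "pct_dma"):
        df[f"logit_{col}"] = logit_percent(df[col].to_numpy())
    df["tap_water_consumption_recoded"] = recode_water_consumption(
        df["tap_water_consumption"].to_numpy()
    )
    df["log10_consumption"] = np.log10(df["tap_water_consumption_recoded"])
    for src, dst in (
        ("water_tas", "log10_water_tas"),
        ("creatinine", "log10_creatinine"),
        ("cotinine", "log10_cotinine"),
        ("bmi", "log10_bmi"),
        ("age", "log10_age"),
    ):
        df[dst] = np.log10(df[src].astype(float))
    if "nail_tas" in df and df["nail_tas"].notna().all():
        df["log10_nail_tas"] = np.log10(df["nail_tas"].astype(float))
    df["smoking_cat"] = smoking_category(
        df["cotinine"].to_numpy(), df["creatinine"].to_numpy()
    )
    df["female"] = (df["gender"] == "female").astype(int)
    df["race_other"] = (df["race"] == "other").astype(int)
    return df
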