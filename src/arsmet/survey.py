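"""Cohort vs reference-survey comparison of urinary arsenic levels.

Implements the comparison procedure: survey-weighted geometric means of
censored analytes via a weighted left-censored log-normal likelihood
(equivalent to a log-normal survival fit), post-stratification of the
reference survey's weights to the cohort's demographic distribution over
gender x race x age bands, and per-species comparison ratios together with
non-detect percentages and mean detection limits on both sides.

The reference survey is any table with species value/`_nd` columns, the
demographic columns and a `weight` column; tests exercise the machinery on a
synthetic reference generated by shifting the cohort generator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .censored import CensoredLogNormalRegression, EstimationError
from .simulate import CohortConfig, generate_cohort_frame, SPECIES

__all__ = [
    "AGE_BANDS",
    "censored_weighted_gm",
    "demographic_distribution",
    "reweight_reference",
    "compare_cohort_to_reference",
    "make_reference_survey",
]

#: age bands used for demographic post-stratification
AGE_BANDS = ((40, 49), (50, 59), (60, 69), (70, 79), (80, np.inf))


def censored_weighted_gm(values, censored, weights=None) -> float:
    """Weighted geometric mean of a left-censored analyte.

    Maximum-likelihood location of a weighted left-censored log-normal
    (censored entries carry their LOD); the GM is 10 ** (fitted mean log10).
    Invariant to rescaling all weights.
    """
    values = np.asarray(values, dtype=float)
    cens = np.asarray(censored, dtype=bool)
    if cens.all():
        raise EstimationError("all values censored: GM is not identified")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights < 0):
            raise ValueError("weights must be non-negative")
        keep = weights > 0  # zero weight: outside the target population
        values, cens, weights = values[keep], cens[keep], weights[keep]
        if cens.all():
            raise EstimationError("all positively weighted values censored")
        weights = weights / weights.mean()  # scale invariance, conditioning
    est = CensoredLogNormalRegression()
    est.fit(None, values, censored=cens, sample_weight=weights)
    return float(10.0 ** est.coef_[0])


def _age_band(age) -> np.ndarray:
    """Label ages with contiguous decade bands (ages below the first band
    edge are folded into the first band)."""
    age = np.asarray(age, dtype=float)
    edges = [lo for lo, _ in AGE_BANDS[1:]]  # 50, 60, 70, 80
    names = [
        f"{lo:.0f}+" if np.isinf(hi) else f"{lo:.0f}-{hi:.0f}"
        for lo, hi in AGE_BANDS
    ]
    idx = np.digitize(age, edges)
    return np.asarray(names, dtype=object)[idx]


def demographic_distribution(frame: pd.DataFrame, weights=None) -> pd.Series:
    """Weighted share of each gender x race x age-band cell."""
    cells = pd.DataFrame(
        {
            "gender": frame["gender"].astype(str),
            "race": frame["race"].astype(str),
            "age_band": _age_band(frame["age"]),
        }
    )
    w = (
        np.ones(len(frame))
        if weights is None
        else np.asarray(weights, dtype=float)
    )
    totals = cells.assign(w=w).groupby(
        ["gender", "race", "age_band"], observed=True
    )["w"].sum()
    return totals / totals.sum()


def reweight_reference(
    reference: pd.DataFrame, target_distribution: pd.Series,
    weight_col: str = "weight",
) -> np.ndarray:
    """Post-stratify reference weights to a target demographic distribution.

    Within each gender x race x age-band cell, weights are rescaled so that
    weighted cell shares equal the target shares; the total weight is
    preserved.  Raises if a cell with positive target share is empty in the
    reference.
    """
    w = reference[weight_col].to_numpy(float)
    cells = pd.MultiIndex.from_arrays(
        [
            reference["gender"].astype(str),
            reference["race"].astype(str),
            _age_band(reference["age"]),
        ],
        names=["gender", "race", "age_band"],
    )
    ref_shares = (
        pd.Series(w, index=cells).groupby(level=[0, 1, 2], observed=True).sum()
    )
    ref_shares = ref_shares / ref_shares.sum()
    missing = [
        cell
        for cell, share in target_distribution.items()
        if share > 0 and cell not in ref_shares.index
    ]
    if missing:
        raise ValueError(
            f"reference survey has no members in target cells: {missing}"
        )
    factors = (target_distribution / ref_shares).reindex(cells).to_numpy()
    factors = np.where(np.isfinite(factors), factors, 0.0)
    new_w = w * factors
    # conserve total weight exactly
    new_w *= w.sum() / new_w.sum()
    return new_w


def compare_cohort_to_reference(
    imputed_sets,
    reference: pd.DataFrame,
    species=SPECIES,
    lods: dict | None = None,
    weight_col: str = "weight",
) -> pd.DataFrame:
    """Per-species comparison of cohort and reweighted reference levels.

    Cohort GMs use completed (imputed) concentrations averaged over the M
    datasets; reference GMs use the weighted censored log-normal fit after
    post-stratifying the reference to the cohort's demographic distribution.
    Returns a table with GMs, their ratio, non-detect percentages and the
    mean detection limit of non-detects on both sides.
    """
    frames = [getattr(s, "frame", s) for s in imputed_sets]
    cohort0 = frames[0]
    for sp in species:
        if sp not in cohort0 or sp not in reference:
            raise ValueError(f"species {sp!r} absent from cohort or reference")

    target = demographic_distribution(cohort0)
    new_w = reweight_reference(reference, target, weight_col=weight_col)

    rows = []
    for sp in species:
        log_gm = np.mean(
            [np.log10(f[sp].to_numpy(float)).mean() for f in frames]
        )
        cohort_gm = float(10.0 ** log_gm)
        ref_nd = reference[f"{sp}_nd"].to_numpy(bool)
        ref_gm = censored_weighted_gm(
            reference[sp].to_numpy(float), ref_nd, new_w
        )
        cohort_nd = (
            cohort0[f"{sp}_nd"].to_numpy(bool)
            if f"{sp}_nd" in cohort0
            else np.zeros(len(cohort0), dtype=bool)
        )
        rows.append(
            {
                "species": sp,
                "cohort_gm": cohort_gm,
                "reference_gm": ref_gm,
                "gm_ratio": cohort_gm / ref_gm,
                "cohort_nondetect_pct": 100.0 * cohort_nd.mean(),
                "reference_nondetect_pct": 100.0
                * float(np.average(ref_nd, weights=new_w)),
                "cohort_mean_lod": (
                    float(cohort0.loc[cohort_nd, sp].mean())
                    if cohort_nd.any()
                    else np.nan
                ),
                "reference_mean_lod": (
                    float(reference.loc[ref_nd, sp].mean())
                    if ref_nd.any()
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def make_reference_survey(
    config: CohortConfig | None = None,
    gm_shift_log10: float = 0.8,
    seed: int | None = 0,
    lods: dict | None = None,
) -> pd.DataFrame:
    """Generate a synthetic reference survey.

    Reuses the cohort generator, shifts every urinary species down by
    `gm_shift_log10` on the log10 scale (a general-population survey sees far
    lower arsenic levels), re-censors at `lods` (defaults to the cohort
    LODs), and attaches log-normal survey weights.
    """
    from .simulate import apply_censoring

    config = config or CohortConfig()
    rng = np.random.default_rng(None if seed is None else seed + 10_000)
    df = generate_cohort_frame(config, seed)
    lods = lods or config.urine_lods
    for sp in SPECIES:
        nd = df[f"{sp}_nd"].to_numpy(bool)
        latent = df[sp].to_numpy(float)
        # censored cells hold the LOD; shift the detected values only, then
        # re-censor everything at the (possibly new) LOD
        shifted = latent * 10.0 ** (-gm_shift_log10)
        vals, flags = apply_censoring(shifted, lods[sp])
        flags = flags | nd  # anything censored before stays censored
        vals = np.where(flags, lods[sp], vals)
        df[sp] = vals
        df[f"{sp}_nd"] = flags
    df["weight"] = 10.0 ** rng.normal(0.0, 0.3, size=len(df))
    return df
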