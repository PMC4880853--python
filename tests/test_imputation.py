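"""Multiple imputation: ranges, properness, moments, correlations."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.stats import norm

from arsmet.imputation import CohortImputer, impute_nondetects
from arsmet.simulate import CohortConfig, generate_cohort_frame
from conftest import null_truth

SPECIES = ("ias3", "ias5", "mma", "dma")


def test_nothing_to_impute_gives_identical_copies():
    cfg = CohortConfig(
        n_participants=150,
        urine_lods={k: 1e-9 for k in SPECIES},
        nail_lod=1e-9,
        water_lod=1e-9,
        missingness_rates={},
    )
    df = generate_cohort_frame(cfg, seed=2)
    sets = impute_nondetects(df, m=3, seed=1)
    assert len(sets) == 3
    for ds in sets:
        pd.testing.assert_frame_equal(
            ds.frame.reset_index(drop=True), df.reset_index(drop=True)
        )
        assert not ds.provenance.to_numpy().any()


def test_default_m_is_twenty(small_cohort):
    imp = CohortImputer()
    assert imp.m == 20
    sets = impute_nondetects(small_cohort.head(150), m=20, seed=0)
    assert len(sets) == 20
    assert [ds.m for ds in sets] == list(range(1, 21))


def test_imputed_cells_strictly_inside_zero_lod(small_cohort, imputed_small):
    for ds in imputed_small:
        for sp in SPECIES + ("water_tas",):
            nd = small_cohort[f"{sp}_nd"].to_numpy(bool)
            imputed = ds.frame.loc[nd, sp].to_numpy()
            lods = small_cohort.loc[nd, sp].to_numpy()  # ND cells hold the LOD
            assert (imputed > 0).all()
            assert (imputed < lods).all()
            # detected cells are untouched
            det = ~nd & np.isfinite(small_cohort[sp].to_numpy(float))
            np.testing.assert_array_equal(
                ds.frame.loc[det, sp].to_numpy(),
                small_cohort.loc[det, sp].to_numpy(),
            )
        assert ds.frame.drop(columns=["id"]).notna().all().all()


def test_between_imputation_variance_positive(small_cohort, imputed_small):
    nd = small_cohort["ias5_nd"].to_numpy(bool)
    stack = np.array([ds.frame.loc[nd, "ias5"].to_numpy() for ds in imputed_small])
    assert (stack.var(axis=0) > 0).mean() > 0.95


def test_deterministic_given_seed(small_cohort):
    a = impute_nondetects(small_cohort, m=2, seed=5)
    b = impute_nondetects(small_cohort, m=2, seed=5)
    for x, y in zip(a, b):
        pd.testing.assert_frame_equal(x.frame, y.frame)


def test_imputed_mean_matches_truncated_lognormal_quadrature():
    """Mean of imputed non-detects ~ E[X | X < LOD] by numerical quadrature.

    A null-truth cohort makes log10 DMA ~ N(alpha, sd) exactly, so the
    truncated mean has an independent quadrature oracle.
    """
    alpha, sd = 0.18, 0.35
    cfg = CohortConfig(
        n_participants=2000,
        truth={
            "tias": null_truth(0.3),
            "mma": null_truth(0.3),
            "dma": null_truth(alpha),
        },
        residual_sd={"tias": 0.3, "mma": 0.3, "dma": sd},
        residual_corr=0.0,
        missingness_rates={},
    )
    df = generate_cohort_frame(cfg, seed=12)
    lod = cfg.urine_lods["dma"]
    nd = df["dma_nd"].to_numpy(bool)
    assert nd.sum() > 100

    log_lod = np.log10(lod)
    num = integrate.quad(
        lambda y: 10.0 ** y * norm.pdf(y, alpha, sd), -10, log_lod
    )[0]
    oracle = num / norm.cdf((log_lod - alpha) / sd)

    m = 20
    sets = impute_nondetects(df, m=m, seed=77)
    per_imp = np.array(
        [ds.frame.loc[nd, "dma"].mean() for ds in sets]
    )
    # Monte-Carlo SE: between-imputation spread plus estimation error of the
    # fitted location (~sd/sqrt(n)) propagated to the concentration scale
    se = np.sqrt(per_imp.var(ddof=1) / m + (oracle * np.log(10) * sd / np.sqrt(len(df))) ** 2)
    assert abs(per_imp.mean() - oracle) < 3 * se


def test_correlation_preserved_after_imputation():
    """Completed-data correlation ~ pre-censoring correlation within 0.1."""
    cfg = CohortConfig(n_participants=2000)
    uncensored_cfg = dataclasses.replace(
        cfg,
        urine_lods={k: 1e-9 for k in SPECIES},
        nail_lod=1e-9,
        water_lod=1e-9,
    )
    seed = 31
    latent = generate_cohort_frame(uncensored_cfg, seed=seed)
    observed = generate_cohort_frame(cfg, seed=seed)
    # identical random draws: only the censoring step differs
    np.testing.assert_allclose(
        latent.loc[~observed["dma_nd"], "dma"],
        observed.loc[~observed["dma_nd"], "dma"],
    )
    r_true = np.corrcoef(np.log10(latent["ias3"]), np.log10(latent["mma"]))[0, 1]
    sets = impute_nondetects(observed, m=5, seed=3)
    r_imp = np.mean(
        [
            np.corrcoef(np.log10(ds.frame["ias3"]), np.log10(ds.frame["mma"]))[0, 1]
            for ds in sets
        ]
    )
    assert abs(r_imp - r_true) < 0.1


def test_m_below_two_rejected(small_cohort):
    with pytest.raises(ValueError):
        impute_nondetects(small_cohort, m=1, seed=0)
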