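"""Synthetic cohort generator: determinism, invariants, censoring."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from arsmet.simulate import (
    CohortConfig,
    ConfigurationError,
    apply_censoring,
    expected_log10_species,
    generate_cohort,
    generate_cohort_frame,
)
from conftest import null_truth


def test_default_cohort_shape_and_water_range(default_config):
    df = generate_cohort_frame(default_config, seed=1)
    assert len(df) == 904
    assert df["water_tas"].max() <= 1850.0
    assert (df["age"] >= 45).all()


def test_seeded_determinism(default_config):
    a = generate_cohort_frame(default_config, seed=5)
    b = generate_cohort_frame(default_config, seed=5)
    pd.testing.assert_frame_equal(a, b)
    c = generate_cohort_frame(default_config, seed=6)
    assert not a["water_tas"].equals(c["water_tas"])


def test_apply_censoring_examples():
    vals, flags = apply_censoring([0.4, 0.6], lod=0.5)
    assert vals.tolist() == [0.5, 0.6]
    assert flags.tolist() == [True, False]
    vals, flags = apply_censoring([], lod=1.0)
    assert vals.size == 0 and flags.size == 0
    with pytest.raises(ValueError):
        apply_censoring([-0.1], lod=0.5)


def test_censoring_fraction_matches_normal_cdf(rng):
    """Non-detect fraction of a log-normal equals the normal CDF at the LOD."""
    sample = 10.0 ** rng.normal(1.0, 1.0, size=200_000)
    _, flags = apply_censoring(sample, lod=3.0)
    expected = norm.cdf((np.log10(3.0) - 1.0) / 1.0)
    se = np.sqrt(expected * (1 - expected) / sample.size)
    assert abs(flags.mean() - expected) < 3 * se


@pytest.mark.parametrize("seed", range(0, 100, 7))
def test_record_invariants_over_seeds(seed):
    cfg = CohortConfig(n_participants=60)
    records = generate_cohort(cfg, seed=seed)
    assert len(records) == 60
    for r in records:
        assert r.water_source in (
            "untreated", "filtered", "other_treatment", "bottled"
        )
        assert r.age >= 45
        assert r.water_tas >= 0 and r.tap_water_consumption >= 0
        # censored cells carry the LOD itself
        if r.urine.ias5_nd:
            assert r.urine.ias5 == cfg.urine_lods["ias5"]
        if r.water_tas_nd:
            assert r.water_tas == cfg.water_lod
        for v in (r.urine.ias3, r.urine.ias5, r.urine.mma, r.urine.dma):
            assert v > 0


def test_covariate_moments_converge():
    """Empirical covariate moments match the configuration at n = 10,000."""
    cfg = CohortConfig(n_participants=10_000)
    df = generate_cohort_frame(cfg, seed=3)
    n = len(df)

    def check_prop(observed, p):
        assert abs(observed - p) < 3 * np.sqrt(p * (1 - p) / n)

    check_prop((df["gender"] == "female").mean(), cfg.covariates.female_prob)
    check_prop(df["recent_fish"].mean(), cfg.covariates.fish_prob)
    check_prop((df["water_source"] == "bottled").mean(),
               cfg.water_source_probs["bottled"])
    mu, sd = cfg.covariates.log10_bmi
    obs = np.log10(df["bmi"].dropna())
    assert abs(obs.mean() - mu) < 3 * sd / np.sqrt(n)


def test_zero_residual_reproduces_mean_structure():
    """With zero residual SD the generated species equal the model mean."""
    cfg = CohortConfig(
        n_participants=500,
        urine_lods={k: 1e-9 for k in ("ias3", "ias5", "mma", "dma")},
        nail_lod=1e-9,
        water_lod=1e-9,
        residual_sd={"tias": 0.0, "mma": 0.0, "dma": 0.0},
        missingness_rates={},
    )
    df = generate_cohort_frame(cfg, seed=9)
    mu = expected_log10_species(cfg, df)
    np.testing.assert_allclose(np.log10(df["dma"]), mu["dma"], atol=1e-9)
    np.testing.assert_allclose(np.log10(df["mma"]), mu["mma"], atol=1e-9)
    np.testing.assert_allclose(
        np.log10(df["ias3"] + df["ias5"]), mu["tias"], atol=1e-9
    )


def test_dma_censoring_rate_matches_configured_target():
    """A config tuned for ~5 % DMA non-detects hits the target empirically.

    With no covariate effects, log10 DMA ~ N(alpha, sd); choosing
    alpha = -sd * z(0.05) above log10(LOD) puts 5 % of draws below the LOD.
    """
    sd = 0.3
    target = 0.05
    alpha = float(np.log10(1.0) - sd * norm.ppf(target))
    cfg = CohortConfig(
        n_participants=10_000,
        truth={
            "tias": null_truth(0.3),
            "mma": null_truth(0.3),
            "dma": null_truth(alpha),
        },
        residual_sd={"tias": 0.3, "mma": 0.3, "dma": sd},
    )
    df = generate_cohort_frame(cfg, seed=4)
    assert abs(df["dma_nd"].mean() - target) < 0.02


@pytest.mark.parametrize(
    "mutate, field",
    [
        (lambda c: setattr(c, "n_participants", 0), "n_participants"),
        (lambda c: c.water_source_probs.update(untreated=0.9), "water_source_probs"),
        (lambda c: c.urine_lods.update(dma=-1.0), "urine_lods"),
        (lambda c: setattr(c.covariates, "age_min", 30), "age_min"),
    ],
)
def test_invalid_config_errors_name_the_field(mutate, field):
    cfg = CohortConfig()
    mutate(cfg)
    with pytest.raises(ConfigurationError, match=field):
        generate_cohort_frame(cfg, seed=0)
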