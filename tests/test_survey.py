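"""Survey comparison: censored weighted GMs, post-stratification, ratios."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from arsmet.censored import EstimationError
from arsmet.simulate import CohortConfig, generate_cohort_frame
from arsmet.survey import (
    censored_weighted_gm,
    compare_cohort_to_reference,
    demographic_distribution,
    make_reference_survey,
    reweight_reference,
)

UNCENSORED = dict(
    urine_lods={k: 1e-9 for k in ("ias3", "ias5", "mma", "dma")},
    nail_lod=1e-9,
    water_lod=1e-9,
    missingness_rates={},
)


def test_uncensored_equal_weights_is_ordinary_gm(rng):
    vals = 10.0 ** rng.normal(0.5, 0.3, 400)
    gm = censored_weighted_gm(vals, np.zeros(400, bool))
    assert gm == pytest.approx(10.0 ** np.log10(vals).mean(), rel=1e-5)


def test_censored_gm_recovers_truth(rng):
    mu, sigma = 0.3, 0.5
    n = 5000
    vals = 10.0 ** rng.normal(mu, sigma, n)
    lod = 10.0 ** mu  # ~50 % censored
    cens = vals < lod
    vals = np.where(cens, lod, vals)
    gm = censored_weighted_gm(vals, cens, np.ones(n))
    se = sigma / np.sqrt(n) * 1.6  # censoring inflates the location SE
    assert abs(np.log10(gm) - mu) < 3 * se


def test_weight_scale_invariance(rng):
    vals = 10.0 ** rng.normal(0.0, 0.4, 300)
    cens = vals < 0.7
    vals = np.where(cens, 0.7, vals)
    w = rng.uniform(0.5, 2.0, 300)
    a = censored_weighted_gm(vals, cens, w)
    b = censored_weighted_gm(vals, cens, 2.0 * w)
    assert a == pytest.approx(b, rel=1e-6)


def test_all_censored_gm_error():
    with pytest.raises(EstimationError):
        censored_weighted_gm([0.5, 0.5], [True, True])


def test_censored_gm_consistency():
    """Bias shrinks as the sample grows."""
    mu, sigma = 0.2, 0.4
    biases = []
    for n in (500, 50_000):
        rng = np.random.default_rng(13)
        vals = 10.0 ** rng.normal(mu, sigma, n)
        lod = 10.0 ** (mu + 0.1)
        cens = vals < lod
        vals = np.where(cens, lod, vals)
        gm = censored_weighted_gm(vals, cens)
        biases.append(abs(np.log10(gm) - mu))
    assert biases[1] < biases[0]


def _demo_frame(genders, races, ages, weights):
    return pd.DataFrame(
        {"gender": genders, "race": races, "age": ages, "weight": weights}
    )


def test_reweight_fixed_point():
    ref = _demo_frame(
        ["male", "female"] * 50, ["white"] * 100,
        [55.0] * 100, np.ones(100),
    )
    target = demographic_distribution(ref, ref["weight"])
    new_w = reweight_reference(ref, target)
    np.testing.assert_allclose(new_w, ref["weight"], rtol=1e-12)


def test_reweight_two_cell_hand_example():
    """Reference shares (0.25, 0.75) moved to (0.5, 0.5): factors 2 and 2/3."""
    ref = _demo_frame(
        ["male"] * 25 + ["female"] * 75,
        ["white"] * 100, [55.0] * 100, np.ones(100),
    )
    target_frame = _demo_frame(
        ["male"] * 50 + ["female"] * 50,
        ["white"] * 100, [55.0] * 100, np.ones(100),
    )
    target = demographic_distribution(target_frame)
    new_w = reweight_reference(ref, target)
    np.testing.assert_allclose(new_w[:25], 2.0, rtol=1e-12)
    np.testing.assert_allclose(new_w[25:], 2.0 / 3.0, rtol=1e-12)
    assert new_w.sum() == pytest.approx(100.0)  # total weight conserved
    # post-stratified shares match the target to near machine precision
    shares = demographic_distribution(ref, new_w)
    for cell, share in target.items():
        assert shares[cell] == pytest.approx(share, abs=1e-12)


def test_reweight_empty_cell_error():
    ref = _demo_frame(["male"] * 10, ["white"] * 10, [55.0] * 10, np.ones(10))
    target_frame = _demo_frame(
        ["male", "female"] * 5, ["white"] * 10, [55.0] * 10, np.ones(10)
    )
    target = demographic_distribution(target_frame)
    with pytest.raises(ValueError, match="female"):
        reweight_reference(ref, target)


def test_reference_equal_to_cohort_gives_unit_ratios():
    cfg = dataclasses.replace(CohortConfig(n_participants=400), **UNCENSORED)
    df = generate_cohort_frame(cfg, seed=30)
    ref = df.copy()
    ref["weight"] = 1.0
    table = compare_cohort_to_reference([df], ref)
    np.testing.assert_allclose(table["gm_ratio"], 1.0, rtol=1e-4)


def test_shifted_reference_ratio_matches_shift_oracle():
    """A -0.8 log10 shift in the reference gives GM ratios near 10^0.8."""
    cfg = dataclasses.replace(CohortConfig(n_participants=3000), **UNCENSORED)
    df = generate_cohort_frame(cfg, seed=31)
    ref = make_reference_survey(
        cfg, gm_shift_log10=0.8, seed=31,
        lods={k: 1e-9 for k in ("ias3", "ias5", "mma", "dma")},
    )
    table = compare_cohort_to_reference([df], ref)
    np.testing.assert_allclose(table["gm_ratio"], 10.0 ** 0.8, rtol=0.1)
    assert {"cohort_nondetect_pct", "reference_nondetect_pct"} <= set(table.columns)


def test_missing_species_rejected(derived_small):
    ref = derived_small[0].copy()
    ref["weight"] = 1.0
    with pytest.raises(ValueError, match="selenium"):
        compare_cohort_to_reference(derived_small, ref, species=("selenium",))
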