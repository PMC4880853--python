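"""Offset dose-response model: transform, fitting, degeneracies."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from arsmet.derived import add_derived_columns
from arsmet.model import (
    ModelParameters,
    OffsetDoseResponseModel,
    WATER_SOURCES,
    fit_offset_model,
    predict_response,
    significance_stars,
    transform_water_as,
)
from arsmet.simulate import CohortConfig, generate_cohort_frame
from conftest import null_truth


@pytest.fixture(scope="module")
def noiseless():
    cfg = CohortConfig(
        n_participants=904,
        urine_lods={k: 1e-9 for k in ("ias3", "ias5", "mma", "dma")},
        nail_lod=1e-9,
        water_lod=1e-9,
        residual_sd={"tias": 0.0, "mma": 0.0, "dma": 0.0},
        missingness_rates={},
    )
    return cfg, add_derived_columns(generate_cohort_frame(cfg, seed=21))


def test_transform_examples():
    assert transform_water_as(0.0, 1.2) == pytest.approx(1.2)
    assert transform_water_as(99.0, 0.0) == pytest.approx(2.0)


@pytest.mark.parametrize("alpha", [-1.0, 0.0, 1.2])
def test_transform_strictly_increasing(alpha):
    grid = np.linspace(0.0, 1850.0, 2000)
    vals = transform_water_as(grid, alpha)
    assert (np.diff(vals) > 0).all()


def test_noiseless_recovery(noiseless):
    """All 16 parameters recovered from noise-free data to < 1e-6."""
    cfg, frame = noiseless
    fr = fit_offset_model(frame, "log10_dma")
    assert np.max(np.abs(fr.estimates - cfg.truth["dma"].to_vector())) < 1e-6
    assert fr.converged


def test_offset_free_fit_matches_ols_oracle(noiseless):
    """With the offset disabled the model is linear and must equal OLS."""
    _, frame = noiseless
    fr = fit_offset_model(frame, "log10_pmi", offset_enabled=False)
    src = frame["water_source"].astype(str).to_numpy()
    s_mat = np.column_stack([(src == s).astype(float) for s in WATER_SOURCES])
    dose = np.log10(frame["water_tas"].to_numpy())
    z = frame[
        ["log10_consumption", "log10_creatinine", "female",
         "log10_bmi", "log10_age", "log10_cotinine", "recent_fish"]
    ].to_numpy(float)
    design = np.hstack([s_mat, s_mat * dose[:, None], z])
    ols = sm.OLS(frame["log10_pmi"].to_numpy(), design).fit()
    np.testing.assert_allclose(fr.estimates, ols.params, atol=1e-8)
    np.testing.assert_allclose(fr.se, ols.bse, atol=1e-8)


def test_row_order_invariance(noiseless):
    _, frame = noiseless
    shuffled = frame.sample(frac=1.0, random_state=3).reset_index(drop=True)
    a = fit_offset_model(frame, "log10_tias")
    b = fit_offset_model(shuffled, "log10_tias")
    np.testing.assert_allclose(a.estimates, b.estimates, atol=1e-7)


def test_profile_sse_unimodal_near_optimum():
    cfg = CohortConfig(n_participants=904)
    frame = add_derived_columns(
        generate_cohort_frame(
            CohortConfig(
                n_participants=904,
                urine_lods={k: 1e-9 for k in ("ias3", "ias5", "mma", "dma")},
                nail_lod=1e-9, water_lod=1e-9, missingness_rates={},
            ),
            seed=6,
        )
    )
    est = OffsetDoseResponseModel(dependent="log10_dma").fit(frame)
    from arsmet.model import _design_components

    s, w, z = _design_components(frame)
    y = frame["log10_dma"].to_numpy()
    a_hat = est.params_.alpha_log_offset
    grid = np.linspace(a_hat - 1.0, a_hat + 1.0, 41)
    sse = np.array([est._profile_sse(a, s, w, z, y)[0] for a in grid])
    mins = np.where((sse[1:-1] <= sse[:-2]) & (sse[1:-1] <= sse[2:]))[0]
    assert len(mins) == 1  # single interior minimum


def test_predict_constant_when_only_intercept():
    params = null_truth(0.7)
    cov = pd.DataFrame(
        {
            "water_source": ["untreated", "bottled"],
            "water_tas": [5.0, 500.0],
            "tap_water_consumption": [1.0, 2.0],
            "creatinine": [100.0, 50.0],
            "gender": ["female", "male"],
            "bmi": [28.0, 30.0],
            "age": [50.0, 70.0],
            "cotinine": [1.0, 1000.0],
            "recent_fish": [0, 1],
        }
    )
    np.testing.assert_allclose(predict_response(params, cov), [0.7, 0.7])


def test_offset_damps_low_dose_response():
    """A larger offset flattens the change from doubling water arsenic."""
    import dataclasses

    base = null_truth(0.0)
    cov = pd.DataFrame(
        {
            "water_source": ["untreated"] * 2,
            "water_tas": [10.0, 20.0],
            "tap_water_consumption": [1.0, 1.0],
            "creatinine": [100.0, 100.0],
            "gender": ["male", "male"],
            "bmi": [28.0, 28.0],
            "age": [60.0, 60.0],
            "cotinine": [1.0, 1.0],
            "recent_fish": [0, 0],
        }
    )
    deltas = []
    for alo in (-3.0, 1.5):
        p = dataclasses.replace(
            base,
            beta={s: 1.0 for s in WATER_SOURCES},
            alpha_log_offset=alo,
        )
        pred = predict_response(p, cov)
        deltas.append(pred[1] - pred[0])
    assert deltas[1] < deltas[0]  # large offset -> damped response
    assert deltas[0] == pytest.approx(np.log10(2.0), abs=1e-3)


def test_unknown_water_source_rejected():
    params = null_truth(0.0)
    cov = pd.DataFrame(
        {
            "water_source": ["rainwater"],
            "water_tas": [5.0],
            "tap_water_consumption": [1.0],
            "creatinine": [100.0],
            "gender": ["male"],
            "bmi": [28.0],
            "age": [60.0],
            "cotinine": [1.0],
            "recent_fish": [0],
        }
    )
    with pytest.raises(ValueError, match="water source"):
        predict_response(params, cov)


def test_significance_star_bins():
    assert significance_stars(5e-5) == "***"
    assert significance_stars(5e-4) == "**"
    assert significance_stars(0.01) == "*"
    assert significance_stars(0.2) == ""


def test_parameter_vector_round_trip():
    p = null_truth(0.3)
    v = p.to_vector()
    q = ModelParameters.from_vector(v, offset_enabled=True)
    assert q == p
    assert len(p.parameter_names()) == v.size
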