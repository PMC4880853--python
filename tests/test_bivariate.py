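"""Bivariate statistics pooled over imputations."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from arsmet.bivariate import (
    age_trend,
    group_geometric_means,
    percentile_range,
    pooled_correlation,
    table1,
)
from arsmet.derived import add_derived_columns
from arsmet.imputation import impute_nondetects
from arsmet.simulate import CohortConfig, generate_cohort_frame


def _frame(values, groups):
    return pd.DataFrame({"v": values, "g": groups})


def test_geometric_mean_closed_form():
    """GM of {10, 1000} is 100."""
    f = _frame([10.0, 1000.0, 10.0, 1000.0, 2.0, 2.0, 2.0],
               ["a", "a", "a", "a", "b", "b", "b"])
    cmp = group_geometric_means([f, f], "v", "g", levels=("a", "b"))
    assert cmp.group_stats["a"] == pytest.approx(100.0)
    assert cmp.group_stats["b"] == pytest.approx(2.0)


def test_group_too_small_rejected():
    f = _frame([1.0, 2.0, 3.0], ["a", "a", "b"])
    with pytest.raises(ValueError):
        group_geometric_means([f], "v", "g", levels=("a", "b"))


def test_correlation_identity_and_sign():
    rng = np.random.default_rng(0)
    x = rng.normal(size=100)
    f1 = pd.DataFrame({"x": x, "y": x})
    r, pooled = pooled_correlation([f1, f1], "x", "y")
    assert r == pytest.approx(1.0, abs=1e-9)
    f2 = pd.DataFrame({"x": x, "y": -x})
    r, _ = pooled_correlation([f2, f2], "x", "y")
    assert r == pytest.approx(-1.0, abs=1e-9)
    with pytest.raises(ValueError):
        pooled_correlation([pd.DataFrame({"x": x, "y": np.ones(100)})], "x", "y")


def test_null_correlation_small():
    """Independent variables at the study sample size: |r| < 0.1 in ~95 %."""
    rng = np.random.default_rng(42)
    ok = 0
    n_seeds = 40
    for _ in range(n_seeds):
        f = pd.DataFrame(
            {"x": rng.normal(size=904), "y": rng.normal(size=904)}
        )
        r, _ = pooled_correlation([f], "x", "y")
        ok += abs(r) < 0.1
    assert ok / n_seeds >= 0.95


def test_percentile_oracle():
    rng = np.random.default_rng(1)
    f = pd.DataFrame({"v": rng.standard_normal(100_000)})
    lo, hi = percentile_range([f], "v", probs=(0.01, 0.99))
    assert lo == pytest.approx(-2.326, abs=0.03)
    assert hi == pytest.approx(2.326, abs=0.03)

    const = pd.DataFrame({"v": np.full(10, 3.5)})
    assert percentile_range([const], "v") == (3.5, 3.5)

    u = pd.DataFrame({"v": rng.uniform(size=1000)})
    lo, hi = percentile_range([u], "v", probs=(0.0, 1.0))
    assert lo == u["v"].min() and hi == u["v"].max()


def test_merged_gm_between_group_gms():
    rng = np.random.default_rng(9)
    a = 10.0 ** rng.normal(0.2, 0.3, 200)
    b = 10.0 ** rng.normal(0.8, 0.3, 300)
    f = _frame(np.concatenate([a, b]), ["a"] * 200 + ["b"] * 300)
    cmp = group_geometric_means([f], "v", "g", levels=("a", "b"))
    merged_gm = 10.0 ** np.log10(f["v"]).mean()
    lo, hi = sorted([cmp.group_stats["a"], cmp.group_stats["b"]])
    assert lo <= merged_gm <= hi


def test_pooled_null_pvalues_roughly_uniform():
    """Under a two-group null the pooled p-values are ~Uniform(0, 1)."""
    rng = np.random.default_rng(17)
    pvals = []
    for _ in range(500):
        base = rng.normal(size=120)
        groups = np.array(["a", "b"]).repeat(60)
        missing = rng.choice(120, size=12, replace=False)  # fixed cells
        frames = []
        for _m in range(5):
            v = base.copy()
            v[missing] = rng.normal(size=12)  # fresh draw per imputation
            frames.append(_frame(10.0 ** v, groups))
        cmp = group_geometric_means(frames, "v", "g", levels=("a", "b"))
        pvals.append(cmp.p_value)
    assert kstest(pvals, "uniform").pvalue > 0.01


def test_power_for_true_gender_difference():
    """A real female deficit in log10 MMA is detected at n = 904."""
    base = CohortConfig()
    truth = dict(base.truth)
    truth["mma"] = dataclasses.replace(truth["mma"], beta_female=-0.25)
    cfg = dataclasses.replace(base, truth=truth)
    hits = 0
    n_seeds = 15
    for s in range(n_seeds):
        df = generate_cohort_frame(cfg, seed=100 + s)
        sets = impute_nondetects(df, m=3, seed=200 + s)
        frames = [add_derived_columns(ds.frame) for ds in sets]
        cmp = group_geometric_means(frames, "mma", "gender",
                                    levels=("male", "female"))
        hits += (cmp.p_value < 0.05) and (
            cmp.group_stats["female"] < cmp.group_stats["male"]
        )
    assert hits / n_seeds >= 0.8


def test_age_trend_detects_slope():
    rng = np.random.default_rng(3)
    age = rng.uniform(45, 92, 500)
    f = pd.DataFrame(
        {"log10_age": np.log10(age),
         "y": 2.0 * np.log10(age) + rng.normal(0, 0.1, 500)}
    )
    pooled = age_trend([f, f], "y")
    assert pooled.estimate == pytest.approx(2.0, abs=0.1)
    assert pooled.p_value < 1e-6


def test_table1_shape(derived_small):
    tab = table1(derived_small)
    assert len(tab) == 8
    assert {"male", "female", "p_value"} <= set(tab.columns)
    assert (tab["p_value"].dropna() <= 1).all()
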