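"""Bivariate analyses pooled over imputations.

Geometric means by group with two-sample tests on the log10 scale,
mean percentages with tests on the logit scale, Fisher-z pooled
correlations, age-trend tests and percentile ranges — each computed on
every completed dataset and combined with the multiple-imputation rules of
:mod:`arsmet.pooling` so reported p-values account for imputation
uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pooling import PooledResult, rubin_pool

__all__ = [
    "GroupComparison",
    "group_geometric_means",
    "group_mean_percent",
    "pooled_correlation",
    "age_trend",
    "percentile_range",
    "table1",
]


def _frames(imputed_sets):
    """Accept ImputedDataset objects or plain DataFrames."""
    return [getattr(s, "frame", s) for s in imputed_sets]


def _pool(estimates, variances) -> PooledResult:
    """Combine per-imputation results; a single completed dataset reduces to
    the ordinary complete-data normal reference (no between-imputation
    variance)."""
    if len(estimates) > 1:
        return rubin_pool(estimates, variances)
    import math

    from scipy import stats as _st

    est, var = float(estimates[0]), float(variances[0])
    t = est / math.sqrt(var) if var > 0 else math.nan
    p = 2.0 * _st.norm.sf(abs(t)) if var > 0 else math.nan
    return PooledResult(
        estimate=est, within_variance=var, between_variance=0.0,
        total_variance=var, df=math.inf, t_stat=t, p_value=p, m=1,
    )


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison of a (transformed) variable, pooled over M."""

    variable: str
    group: str
    levels: tuple[str, str]
    group_stats: dict  # level -> back-transformed group summary
    difference: PooledResult  # level[0] minus level[1] on the analysis scale

    @property
    def p_value(self) -> float:
        return self.difference.p_value


def _two_sample(values, labels, levels):
    """Mean difference (levels[0] - levels[1]) and its pooled-variance SE."""
    a = values[labels == levels[0]]
    b = values[labels == levels[1]]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 members")
    var_pooled = (
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
        / (a.size + b.size - 2)
    )
    se2 = var_pooled * (1.0 / a.size + 1.0 / b.size)
    return float(a.mean() - b.mean()), float(se2), float(a.mean()), float(b.mean())


def group_geometric_means(
    imputed_sets, variable: str, group: str, levels=None
) -> GroupComparison:
    """Per-group geometric means and a pooled test of their difference.

    The test compares mean log10 values between the two groups in each
    completed dataset; estimates and variances are combined across
    imputations, and group GMs are 10 ** (pooled mean log10).
    """
    frames = _frames(imputed_sets)
    if levels is None:
        levels = tuple(pd.unique(frames[0][group].astype(str)))[:2]
    if len(levels) != 2:
        raise ValueError("group comparison requires exactly two levels")
    diffs, variances = [], []
    means = {lv: [] for lv in levels}
    for f in frames:
        vals = f[variable].to_numpy(float)
        if np.any(vals <= 0):
            raise ValueError(f"{variable!r} must be strictly positive for a GM")
        logs = np.log10(vals)
        labels = f[group].astype(str).to_numpy()
        d, v, ma, mb = _two_sample(logs, labels, levels)
        diffs.append(d)
        variances.append(v)
        means[levels[0]].append(ma)
        means[levels[1]].append(mb)
    pooled = _pool(diffs, variances)
    stats = {lv: 10.0 ** float(np.mean(means[lv])) for lv in levels}
    return GroupComparison(
        variable=variable, group=group, levels=tuple(levels),
        group_stats=stats, difference=pooled,
    )


def group_mean_percent(
    imputed_sets, variable: str, group: str, levels=None
) -> GroupComparison:
    """Per-group mean percentages; the test runs on the logit scale."""
    from .derived import logit_percent

    frames = _frames(imputed_sets)
    if levels is None:
        levels = tuple(pd.unique(frames[0][group].astype(str)))[:2]
    diffs, variances = [], []
    means = {lv: [] for lv in levels}
    for f in frames:
        pct = f[variable].to_numpy(float)
        logits = np.asarray(logit_percent(pct))
        labels = f[group].astype(str).to_numpy()
        d, v, _, _ = _two_sample(logits, labels, levels)
        diffs.append(d)
        variances.append(v)
        for lv in levels:
            means[lv].append(float(pct[labels == lv].mean()))
    pooled = _pool(diffs, variances)
    stats = {lv: float(np.mean(means[lv])) for lv in levels}
    return GroupComparison(
        variable=variable, group=group, levels=tuple(levels),
        group_stats=stats, difference=pooled,
    )


def pooled_correlation(imputed_sets, x: str, y: str):
    """Pearson correlation of two (pre-transformed) columns, pooled on the
    Fisher-z scale with variance 1/(n-3).

    Returns ``(r, PooledResult)`` where `r` is the back-transformed pooled
    correlation and the PooledResult tests z = 0.
    """
    zs, variances = [], []
    for f in _frames(imputed_sets):
        xv = f[x].to_numpy(float)
        yv = f[y].to_numpy(float)
        if xv.std() == 0 or yv.std() == 0:
            raise ValueError("zero variance: correlation undefined")
        r = float(np.corrcoef(xv, yv)[0, 1])
        r = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
        zs.append(np.arctanh(r))
        variances.append(1.0 / (xv.size - 3))
    pooled = _pool(zs, variances)
    return float(np.tanh(pooled.estimate)), pooled


def age_trend(imputed_sets, variable: str, age_col: str = "log10_age"):
    """Linear trend of a transformed outcome against log10 age, pooled.

    Returns the pooled slope as a :class:`PooledResult`.
    """
    slopes, variances = [], []
    for f in _frames(imputed_sets):
        x = f[age_col].to_numpy(float)
        y = f[variable].to_numpy(float)
        n = x.size
        xc = x - x.mean()
        sxx = float(xc @ xc)
        slope = float(xc @ y) / sxx
        resid = y - y.mean() - slope * xc
        se2 = float(resid @ resid) / (n - 2) / sxx
        slopes.append(slope)
        variances.append(se2)
    return _pool(slopes, variances)


def percentile_range(imputed_sets, variable: str, probs=(0.01, 0.99)):
    """Percentiles of a variable computed across all completed datasets
    pooled into one sample (linear interpolation between order statistics).
    """
    values = np.concatenate(
        [f[variable].to_numpy(float) for f in _frames(imputed_sets)]
    )
    if values.size == 0:
        raise ValueError("no observations")
    return tuple(np.percentile(values, [100.0 * p for p in probs]))


def table1(imputed_sets, group: str = "gender", levels=("male", "female")):
    """Group summary table: GMs of the concentration variables and indices,
    mean percentages, with pooled p-values."""
    rows = []
    for var, kind in (
        ("tias", "gm"), ("pct_tias", "pct"),
        ("mma", "gm"), ("pct_mma", "pct"),
        ("dma", "gm"), ("pct_dma", "pct"),
        ("pmi", "gm"), ("smi", "gm"),
    ):
        fn = group_geometric_means if kind == "gm" else group_mean_percent
        cmp = fn(imputed_sets, var, group, levels=levels)
        rows.append(
            {
                "variable": var,
                "statistic": "geometric_mean" if kind == "gm" else "mean_percent",
                levels[0]: cmp.group_stats[levels[0]],
                levels[1]: cmp.group_stats[levels[1]],
                "p_value": cmp.p_value,
            }
        )
    return pd.DataFrame(rows)
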