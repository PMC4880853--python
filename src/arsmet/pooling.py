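"""Combining rules for multiply-imputed analyses.

Each completed dataset yields an estimate and a squared standard error for
every quantity of interest.  The rules below combine the M per-imputation
results into a single estimate whose variance has a within-imputation part W
(average sampling variance) and a between-imputation part B (variance of the
estimates across completed datasets), the latter carrying the price paid for
not observing the censored or missing cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["PooledResult", "rubin_pool", "pool_table"]


@dataclass(frozen=True)
class PooledResult:
    """Combined estimate for one parameter across M imputations.

    Attributes
    ----------
    estimate : pooled point estimate (mean of per-imputation estimates).
    within_variance : W, mean of the per-imputation squared standard errors.
    between_variance : B, sample variance of the estimates across imputations.
    total_variance : T = W + (1 + 1/M) B.
    df : reference degrees of freedom (inf when B == 0).
    t_stat : estimate / sqrt(T); nan when T == 0.
    p_value : two-sided p from the t (or normal when df is inf) reference.
    m : number of imputations combined.
    """

    estimate: float
    within_variance: float
    between_variance: float
    total_variance: float
    df: float
    t_stat: float
    p_value: float
    m: int

    @property
    def se(self) -> float:
        return math.sqrt(self.total_variance)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided confidence interval at the given level."""
        alpha = 1.0 - level
        if math.isinf(self.df):
            crit = stats.norm.ppf(1 - alpha / 2)
        else:
            crit = stats.t.ppf(1 - alpha / 2, self.df)
        half = crit * self.se
        return (self.estimate - half, self.estimate + half)


def rubin_pool(
    estimates: Sequence[float], variances: Sequence[float]
) -> PooledResult:
    """Combine per-imputation estimates and variances.

    Parameters
    ----------
    estimates : point estimates, one per completed dataset.
    variances : squared standard errors, one per completed dataset.

    The pooled estimate is the mean of `estimates`; its total variance is
    ``W + (1 + 1/M) B``.  The degrees of freedom follow the classic
    large-sample rule ``(M - 1) (1 + W / ((1 + 1/M) B))**2``; when B is zero
    (identical estimates) the normal reference is used.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1:
        raise ValueError(
            f"estimates and variances must be 1-d and equal length, "
            f"got {q.shape} and {u.shape}"
        )
    m = q.size
    if m < 2:
        raise ValueError("pooling requires at least 2 imputations")
    if np.any(u < 0):
        raise ValueError("variances must be non-negative")

    qbar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1))
    t = w + (1.0 + 1.0 / m) * b

    if b == 0.0:
        df = math.inf
    else:
        df = (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2

    if t == 0.0:
        t_stat = math.nan
        p = math.nan
    else:
        t_stat = qbar / math.sqrt(t)
        if math.isinf(df):
            p = 2.0 * stats.norm.sf(abs(t_stat))
        else:
            p = 2.0 * stats.t.sf(abs(t_stat), df)

    return PooledResult(
        estimate=qbar,
        within_variance=w,
        between_variance=b,
        total_variance=t,
        df=df,
        t_stat=t_stat,
        p_value=p,
        m=m,
    )


def pool_table(frames, estimate_col="estimate", se_col="se", by="parameter"):
    """Pool a stack of per-imputation parameter tables.

    Parameters
    ----------
    frames : iterable of DataFrames with one row per parameter, each carrying
        `estimate_col` and `se_col`.
    by : column identifying the parameter across frames.

    Returns
    -------
    DataFrame indexed like the first frame with pooled estimate, se, df,
    t, p-value and the variance components.
    """
    import pandas as pd

    frames = list(frames)
    if not frames:
        raise ValueError("no per-imputation tables to pool")
    keys = frames[0][by].tolist()
    rows = []
    for key in keys:
        ests = [float(f.loc[f[by] == key, estimate_col].iloc[0]) for f in frames]
        ses = [float(f.loc[f[by] == key, se_col].iloc[0]) for f in frames]
        res = rubin_pool(ests, [s * s for s in ses])
        rows.append(
            {
                by: key,
                "estimate": res.estimate,
                "se": res.se,
                "df": res.df,
                "t": res.t_stat,
                "p_value": res.p_value,
                "within_variance": res.within_variance,
                "between_variance": res.between_variance,
            }
        )
    return pd.DataFrame(rows)
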