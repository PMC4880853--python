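"""Stepwise candidate-predictor selection across imputations.

For every combination of dependent variable (nine arsenic biomarkers) and
completed dataset (M imputations; 9 x 20 = 180 runs by default) a
bidirectional stepwise linear selection is run over the candidate roster,
with interactions (and the quadratic water term) eligible only once their
main effects are in the model.  Per-candidate selection counts are tallied
over all runs; a candidate selected in more than `threshold` (default 25)
runs is retained.  The retained set is then revised into the final model
structure: the cotinine measurement supersedes the categorical smoking
variable, any combination of water-related terms is replaced by the
water-source x transformed-TAs interaction structure, and the recent
fish/shellfish indicator is forced in.

Two selection criteria are available.  The default, ``"bic"``, mirrors the
default model-selection criterion of the general stepwise procedure this
analysis style is based on (entry/removal decided by Schwarz-criterion
improvement).  ``"pvalue"`` uses classical entry/stay significance levels
(default 0.15/0.15).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CandidateSet",
    "SelectionTally",
    "default_candidates",
    "run_stepwise",
    "retain_predictors",
    "revise_selection",
    "FINAL_MODEL_TERMS",
]

#: Terms present in the final dose-response model after revision.
WATER_STRUCTURE = "water_source_by_tas"
FINAL_MODEL_TERMS = (
    WATER_STRUCTURE,
    "log10_consumption",
    "log10_creatinine",
    "female",
    "log10_bmi",
    "log10_age",
    "log10_cotinine",
    "recent_fish",
)

#: candidates whose water-related selections are folded into the
#: water-source x TAs structure during revision
_WATER_TERMS = frozenset(
    {
        "log10_water_tas",
        "log10_water_tas_sq",
        "water_source",
        "water_source_x_log10_water_tas",
        WATER_STRUCTURE,
    }
)


@dataclass(frozen=True)
class CandidateSet:
    """Candidate predictors as named column groups with hierarchy rules.

    `groups` maps a candidate name to the list of design columns it
    contributes (categorical candidates contribute several).  `requires`
    maps a candidate to the set of candidates that must already be in the
    model before it may enter (interaction / quadratic hierarchy).
    """

    groups: dict
    requires: dict = field(default_factory=dict)

    def names(self):
        return list(self.groups)


def default_candidates() -> CandidateSet:
    """The default candidate roster: biological factors (gender, race, BMI,
    age, creatinine), behavioral factors (smoking category, cotinine,
    recent alcohol, recent fish), and water-exposure characteristics (water
    TAs linear + quadratic, source category, daily consumption, and the
    source x TAs interaction)."""
    groups = {
        "female": ["female"],
        "race_other": ["race_other"],
        "log10_bmi": ["log10_bmi"],
        "log10_age": ["log10_age"],
        "log10_creatinine": ["log10_creatinine"],
        "smoking_cat": ["smoking_cat"],
        "log10_cotinine": ["log10_cotinine"],
        "recent_alcohol": ["recent_alcohol"],
        "recent_fish": ["recent_fish"],
        "log10_water_tas": ["log10_water_tas"],
        "log10_water_tas_sq": ["log10_water_tas_sq"],
        "water_source": ["source_filtered", "source_other_treatment", "source_bottled"],
        "log10_consumption": ["log10_consumption"],
        "water_source_x_log10_water_tas": [
            "source_filtered_x_tas",
            "source_other_treatment_x_tas",
            "source_bottled_x_tas",
        ],
    }
    requires = {
        "log10_water_tas_sq": {"log10_water_tas"},
        "water_source_x_log10_water_tas": {"water_source", "log10_water_tas"},
    }
    return CandidateSet(groups=groups, requires=requires)


def build_selection_design(frame: pd.DataFrame) -> pd.DataFrame:
    """Add the selection-only columns (quadratic and interaction terms,
    source dummies) to a derived cohort frame."""
    df = frame.copy()
    if "log10_water_tas" in df:
        df["log10_water_tas_sq"] = df["log10_water_tas"] ** 2
    if "water_source" in df:
        src = df["water_source"].astype(str)
        for s in ("filtered", "other_treatment", "bottled"):
            df[f"source_{s}"] = (src == s).astype(float)
            if "log10_water_tas" in df:
                df[f"source_{s}_x_tas"] = (
                    df[f"source_{s}"] * df["log10_water_tas"]
                )
    return df


@dataclass
class SelectionTally:
    """Per-candidate selection counts over dependent x imputation runs."""

    counts: dict
    total_runs: int
    planned_runs: int

    def as_frame(self, threshold: int = 25) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "candidate": list(self.counts),
                "count": list(self.counts.values()),
                "total_runs": self.total_runs,
                "retained": [c > threshold for c in self.counts.values()],
            }
        )


class _RunDesign:
    """Per-run cached design columns and response."""

    def __init__(self, frame, candidates: CandidateSet, dependent: str):
        self.y = frame[dependent].to_numpy(float)
        self.n = self.y.size
        self.cols = {
            name: frame[cols].to_numpy(float)
            for name, cols in candidates.groups.items()
        }
        self.intercept = np.ones((self.n, 1))

    def design(self, model):
        return np.hstack([self.intercept] + [self.cols[name] for name in model])


def _fit_sse(x, y):
    coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < x.shape[1]:
        return None, None  # rank-deficient: collinear addition
    resid = y - x @ coef
    return float(resid @ resid), x.shape[1]


def _bic(sse, n, k):
    return n * np.log(sse / n) + k * np.log(n)


def _stepwise_single(
    rd: _RunDesign,
    candidates: CandidateSet,
    criterion: str,
    sle: float,
    sls: float,
    max_steps: int = 60,
) -> list:
    model: list[str] = []
    sse_cur, k_cur = _fit_sse(rd.design(model), rd.y)
    if sse_cur is None:
        raise np.linalg.LinAlgError("intercept-only design singular")
    requires = candidates.requires
    names = candidates.names()

    for _ in range(max_steps):
        changed = False

        # --- entry step
        best = None
        for name in names:
            if name in model:
                continue
            if not requires.get(name, set()) <= set(model):
                continue
            x = rd.design(model + [name])
            sse_new, k_new = _fit_sse(x, rd.y)
            if sse_new is None:
                continue  # perfectly collinear with the current model
            df_num = k_new - k_cur
            df_den = rd.n - k_new
            if df_den <= 0 or sse_new <= 0:
                continue
            if criterion == "pvalue":
                f = (sse_cur - sse_new) / df_num / (sse_new / df_den)
                p = stats.f.sf(f, df_num, df_den)
                score = p
                ok = p < sle
            else:
                score = _bic(sse_new, rd.n, k_new)
                ok = score < _bic(sse_cur, rd.n, k_cur) - 1e-9
            if ok and (best is None or score < best[0]):
                best = (score, name, sse_new, k_new)
        if best is not None:
            model.append(best[1])
            sse_cur, k_cur = best[2], best[3]
            changed = True

        # --- removal step (never remove a term another in-model term needs)
        worst = None
        for name in model:
            if any(name in requires.get(o, set()) for o in model if o != name):
                continue
            reduced = [m for m in model if m != name]
            sse_red, k_red = _fit_sse(rd.design(reduced), rd.y)
            if sse_red is None:
                continue
            df_num = k_cur - k_red
            df_den = rd.n - k_cur
            if criterion == "pvalue":
                f = (sse_red - sse_cur) / df_num / (sse_cur / df_den)
                p = stats.f.sf(f, df_num, df_den)
                if p > sls and (worst is None or p > worst[0]):
                    worst = (p, name, sse_red, k_red)
            else:
                score = _bic(sse_red, rd.n, k_red)
                if score < _bic(sse_cur, rd.n, k_cur) - 1e-9 and (
                    worst is None or score < worst[0]
                ):
                    worst = (score, name, sse_red, k_red)
        if worst is not None:
            entered = best[1] if best is not None else None
            if worst[1] == entered:
                # entering then immediately removing: stable point reached
                model.remove(worst[1])
                break
            model.remove(worst[1])
            sse_cur, k_cur = worst[2], worst[3]
            changed = True

        if not changed:
            break
    return model


def run_stepwise(
    imputed_sets,
    dependents,
    candidates: CandidateSet | None = None,
    criterion: str = "bic",
    sle: float = 0.15,
    sls: float = 0.15,
) -> SelectionTally:
    """Tally stepwise selections over all dependent x imputation runs.

    `imputed_sets` are completed, derived cohort frames (or ImputedDataset);
    selection-only columns are added automatically.  Runs whose design is
    singular are skipped with a warning and reduce the effective total.
    """
    if criterion not in ("bic", "pvalue"):
        raise ValueError("criterion must be 'bic' or 'pvalue'")
    candidates = candidates or default_candidates()
    frames = [
        build_selection_design(getattr(s, "frame", s)) for s in imputed_sets
    ]
    counts = {name: 0 for name in candidates.names()}
    planned = len(frames) * len(dependents)
    completed = 0
    for dep in dependents:
        for f in frames:
            rd = _RunDesign(f, candidates, dep)
            try:
                model = _stepwise_single(rd, candidates, criterion, sle, sls)
            except np.linalg.LinAlgError as exc:
                warnings.warn(
                    f"skipping singular run for {dep!r}: {exc}", RuntimeWarning
                )
                continue
            completed += 1
            for name in model:
                counts[name] += 1
    return SelectionTally(counts=counts, total_runs=completed, planned_runs=planned)


def retain_predictors(tally: SelectionTally, threshold: int = 25) -> set:
    """Retain candidates selected in strictly more than `threshold` runs."""
    if threshold >= tally.total_runs:
        raise ValueError("threshold must be below the number of runs")
    return {name for name, c in tally.counts.items() if c > threshold}


def revise_selection(retained: set) -> list:
    """Post-hoc revision of the retained set into the final model terms.

    * the cotinine measurement supersedes the categorical smoking variable;
    * any selected water-related terms (TAs linear/quadratic, source,
      source x TAs) are replaced by the water-source x transformed-TAs
      structure (per-source intercepts and slopes), which is always present;
    * the recent fish/shellfish indicator is forced in.

    Returns the final term list in canonical order.
    """
    final = set(retained)
    if "smoking_cat" in final:
        final.discard("smoking_cat")
        final.add("log10_cotinine")
    final -= _WATER_TERMS
    final.add(WATER_STRUCTURE)
    final.add("recent_fish")
    ordered = [t for t in FINAL_MODEL_TERMS if t in final]
    extras = sorted(final - set(FINAL_MODEL_TERMS))
    return ordered + extras
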