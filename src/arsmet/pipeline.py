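"""End-to-end analysis pipeline and artifact writers.

Orchestrates simulate -> impute -> derive -> bivariate -> select -> fit ->
pool -> compare -> report as a seeded, logged run writing CSV artifacts to a
run directory.  One global seed fans out to per-stage child seeds through
`numpy.random.SeedSequence(seed).spawn`, so each stage is independently
reproducible from saved intermediates: re-running any stage with the same
global seed rewrites byte-identical downstream artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bivariate import age_trend, percentile_range, pooled_correlation, table1
from .derived import DEPENDENT_VARIABLES, add_derived_columns
from .imputation import CohortImputer
from .model import fit_offset_model, predict_response, significance_stars
from .pooling import pool_table
from .selection import retain_predictors, revise_selection, run_stepwise
from .simulate import (
    CohortConfig,
    generate_cohort_frame,
    read_cohort_csv,
    write_cohort_csv,
    write_truth_csv,
)
from .survey import compare_cohort_to_reference, make_reference_survey

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

#: dependents fitted with the estimated water offset (absolute levels);
#: relative levels and indices use the plain log10 water term
OFFSET_DEPENDENTS = ("log10_tias", "log10_mma", "log10_dma", "log10_usas")

_STAGE_NAMES = ("simulate", "impute", "select", "compare")


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    m: int = 20
    seed: int = 0
    outdir: str = "arsmet_run"
    selection_threshold: int = 25
    selection_criterion: str = "bic"
    dependents: tuple = DEPENDENT_VARIABLES
    offset_dependents: tuple = OFFSET_DEPENDENTS
    reference_gm_shift: float = 0.8


def _stage_seed(config: PipelineConfig, stage: str) -> np.random.SeedSequence:
    idx = _STAGE_NAMES.index(stage)
    return np.random.SeedSequence(config.seed).spawn(len(_STAGE_NAMES))[idx]


def _seed_int(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1)[0] % (2**31))


def load_config(path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML file.

    Top-level keys map to :class:`PipelineConfig` fields; the `cohort` block
    maps to :class:`CohortConfig` (covariate sub-block to
    `CovariateDistributions`).  Omitted keys keep their defaults.
    """
    import yaml

    from .simulate import CovariateDistributions

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort_raw = raw.pop("cohort", {}) or {}
    cov_raw = cohort_raw.pop("covariates", {}) or {}
    cov = CovariateDistributions(**cov_raw)
    cohort = CohortConfig(covariates=cov, **cohort_raw)
    cfg = PipelineConfig(cohort=cohort, **raw)
    if isinstance(cfg.dependents, list):
        cfg.dependents = tuple(cfg.dependents)
    return cfg


# ----------------------------------------------------------------------
# stages
# ----------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, outdir: Path) -> Path:
    seed = _seed_int(_stage_seed(config, "simulate"))
    df = generate_cohort_frame(config.cohort, seed)
    write_cohort_csv(df, outdir / "cohort.csv")
    write_truth_csv(config.cohort, outdir / "truth.csv")
    return outdir / "cohort.csv"


def stage_impute(config: PipelineConfig, outdir: Path) -> list[Path]:
    df = read_cohort_csv(outdir / "cohort.csv")
    seed = _seed_int(_stage_seed(config, "impute"))
    imputer = CohortImputer(m=config.m, random_state=seed)
    sets = imputer.fit_transform(df)
    paths = []
    prov_frames = []
    for ds in sets:
        p = outdir / f"imputed_m{ds.m:02d}.csv"
        ds.frame.to_csv(p, index=False)
        paths.append(p)
        prov = ds.provenance.copy()
        prov.insert(0, "m", ds.m)
        prov_frames.append(prov)
    pd.concat(prov_frames).to_csv(outdir / "imputed_cells.csv", index=False)
    return paths


def _imputed_frames(config: PipelineConfig, outdir: Path) -> list[pd.DataFrame]:
    return [
        read_cohort_csv(outdir / f"imputed_m{i:02d}.csv")
        for i in range(1, config.m + 1)
    ]


def stage_derive(config: PipelineConfig, outdir: Path) -> list[Path]:
    paths = []
    for i, frame in enumerate(_imputed_frames(config, outdir), start=1):
        d = add_derived_columns(frame)
        p = outdir / f"derived_m{i:02d}.csv"
        d.to_csv(p, index=False)
        paths.append(p)
    return paths


def _derived_frames(config: PipelineConfig, outdir: Path) -> list[pd.DataFrame]:
    return [
        pd.read_csv(outdir / f"derived_m{i:02d}.csv")
        for i in range(1, config.m + 1)
    ]


def stage_bivariate(config: PipelineConfig, outdir: Path) -> None:
    frames = _derived_frames(config, outdir)
    table1(frames).to_csv(outdir / "table1.csv", index=False)

    pairs = [
        ("log10_water_tas", v) for v in ("log10_tias", "log10_mma", "log10_dma")
    ] + [
        ("log10_nail_tas", v) for v in ("log10_tias", "log10_mma", "log10_dma")
    ]
    rows = []
    for x, v in pairs:
        if x not in frames[0]:
            continue
        r, pooled = pooled_correlation(frames, x, v)
        rows.append({"x": x, "y": v, "r": r, "p_value": pooled.p_value})
    for v in DEPENDENT_VARIABLES:
        trend = age_trend(frames, v)
        rows.append(
            {"x": "log10_age(trend)", "y": v, "r": trend.estimate,
             "p_value": trend.p_value}
        )
    pd.DataFrame(rows).to_csv(outdir / "correlations.csv", index=False)

    prows = []
    for v in ("pct_tias", "pct_mma", "pct_dma", "pmi", "smi"):
        lo, hi = percentile_range(frames, v)
        prows.append({"variable": v, "p01": lo, "p99": hi})
    pd.DataFrame(prows).to_csv(outdir / "percentiles.csv", index=False)


def stage_select(config: PipelineConfig, outdir: Path) -> None:
    frames = _derived_frames(config, outdir)
    tally = run_stepwise(
        frames, config.dependents, criterion=config.selection_criterion
    )
    # the retention threshold is defined against a 9-dependent x 20-imputation
    # grid (180 runs); smaller smoke runs scale it proportionally
    threshold = config.selection_threshold
    if threshold >= tally.total_runs:
        threshold = int(threshold * tally.total_runs / 180.0)
    retained = retain_predictors(tally, threshold)
    final = revise_selection(retained)
    tab = tally.as_frame(threshold)
    tab["in_final_model"] = [
        c in final or c == "recent_fish" for c in tab["candidate"]
    ]
    tab.to_csv(outdir / "selection_tally.csv", index=False)
    (outdir / "final_terms.json").write_text(json.dumps(final, indent=1))


def stage_fit(config: PipelineConfig, outdir: Path) -> None:
    frames = _derived_frames(config, outdir)
    rows = []
    for dep in config.dependents:
        offset = dep in config.offset_dependents
        for i, f in enumerate(frames, start=1):
            fr = fit_offset_model(f, dep, offset_enabled=offset, imputation=i)
            t = fr.table()
            t.insert(0, "dependent", dep)
            t.insert(1, "m", i)
            rows.append(t)
    pd.concat(rows).to_csv(outdir / "fits.csv", index=False)


def stage_pool(config: PipelineConfig, outdir: Path) -> None:
    fits = pd.read_csv(outdir / "fits.csv")
    pooled_all = []
    for dep, grp in fits.groupby("dependent", sort=False):
        frames = [g for _, g in grp.groupby("m", sort=True)]
        pooled = pool_table(frames)
        pooled.insert(0, "dependent", dep)
        pooled["stars"] = [significance_stars(p) for p in pooled["p_value"]]
        pooled_all.append(pooled)
    out = pd.concat(pooled_all)
    out.to_csv(outdir / "pooled_models.csv", index=False)
    # Human-readable per-dependent report with significance stars
    lines = []
    for dep, grp in out.groupby("dependent", sort=False):
        lines.append(f"== {dep} ==")
        for _, r in grp.iterrows():
            lines.append(
                f"  {r['parameter']:<24s} {r['estimate']:8.3f}{r['stars']:<3s}"
                f" ({r['se']:.3f})"
            )
    (outdir / "pooled_models.txt").write_text("\n".join(lines) + "\n")


def stage_compare(config: PipelineConfig, outdir: Path) -> None:
    frames = _imputed_frames(config, outdir)
    seed = _seed_int(_stage_seed(config, "compare"))
    # a larger reference keeps every demographic cell populated
    ref_cfg = dataclasses.replace(
        config.cohort,
        n_participants=max(5 * config.cohort.n_participants, 2000),
    )
    reference = make_reference_survey(
        ref_cfg, gm_shift_log10=config.reference_gm_shift, seed=seed
    )
    cohort_raw = read_cohort_csv(outdir / "cohort.csv")
    # non-detect flags come from the raw cohort; concentrations from imputed
    for f in frames:
        for sp in ("ias3", "ias5", "mma", "dma"):
            f[f"{sp}_nd"] = cohort_raw[f"{sp}_nd"].to_numpy()
    comparison = compare_cohort_to_reference(frames, reference)
    comparison.to_csv(outdir / "comparison.csv", index=False)


def stage_report(config: PipelineConfig, outdir: Path) -> None:
    """Prediction curves per water source (covariates held at cohort means)."""
    frames = _derived_frames(config, outdir)
    fits = pd.read_csv(outdir / "pooled_models.csv")
    d0 = pd.concat(frames)
    water_grid = np.geomspace(0.5, config.cohort.covariates.water_tas_max, 60)
    rows = []
    from .model import ModelParameters, WATER_SOURCES, parameter_names

    for dep in ("log10_tias", "log10_mma", "log10_dma"):
        grp = fits[fits["dependent"] == dep].set_index("parameter")["estimate"]
        params = ModelParameters.from_vector(
            grp.loc[parameter_names(True)].to_numpy(), offset_enabled=True
        )
        for src in WATER_SOURCES:
            cov = pd.DataFrame(
                {
                    "water_source": src,
                    "water_tas": water_grid,
                    "log10_consumption": d0["log10_consumption"].mean(),
                    "log10_creatinine": d0["log10_creatinine"].mean(),
                    "female": d0["female"].mean(),
                    "log10_bmi": d0["log10_bmi"].mean(),
                    "log10_age": d0["log10_age"].mean(),
                    "log10_cotinine": d0["log10_cotinine"].mean(),
                    "recent_fish": d0["recent_fish"].mean(),
                }
            )
            pred = predict_response(params, cov)
            for w, p in zip(water_grid, pred):
                rows.append(
                    {
                        "dependent": dep,
                        "water_source": src,
                        "water_tas": w,
                        "predicted_ug_per_l": 10.0 ** p,
                    }
                )
    pd.DataFrame(rows).to_csv(outdir / "predicted_curves.csv", index=False)

    log = {
        "arsmet_version": __version__,
        "seed": config.seed,
        "m": config.m,
        "n_participants": config.cohort.n_participants,
        "stage_seeds": {
            s: _seed_int(_stage_seed(config, s)) for s in _STAGE_NAMES
        },
        "dependents": list(config.dependents),
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=1))


_STAGES = {
    "simulate": stage_simulate,
    "impute": stage_impute,
    "derive": stage_derive,
    "bivariate": stage_bivariate,
    "select": stage_select,
    "fit": stage_fit,
    "pool": stage_pool,
    "compare": stage_compare,
    "report": stage_report,
}

STAGE_ORDER = tuple(_STAGES)


def run_stage(name: str, config: PipelineConfig, outdir: Path):
    if name not in _STAGES:
        raise ValueError(f"unknown stage {name!r}")
    try:
        return _STAGES[name](config, outdir)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def run_pipeline(config: PipelineConfig | str | Path) -> Path:
    """Run every stage in order; returns the run directory."""
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in STAGE_ORDER:
        run_stage(name, config, outdir)
    return outdir
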