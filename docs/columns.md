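# Column dictionary

## Cohort table (`cohort.csv`, `imputed_m*.csv`)

| column | units / values | description |
|---|---|---|
| `id` | integer | participant identifier |
| `gender` | `female` / `male` | self-reported gender |
| `age` | years | age at enrollment (>= 45) |
| `bmi` | kg/m2 | body mass index (may be missing pre-imputation) |
| `race` | `white` / `other` | self-reported race |
| `water_source` | `untreated`, `filtered`, `other_treatment`, `bottled` | primary in-home drinking-water source |
| `water_tas` | ug/L | home tap-water total arsenic; holds the LOD (3) when `water_tas_nd` |
| `water_tas_nd` | bool | water arsenic below the detection limit |
| `tap_water_consumption` | L/day | self-reported daily tap-water intake (may be 0) |
| `cotinine` | ug/L | urinary cotinine (smoking biomarker) |
| `creatinine` | mg/dL | urinary creatinine |
| `recent_fish` | 0/1 | fish or shellfish consumed in the previous 48 h |
| `recent_alcohol` | 0/1 | recent alcohol consumption |
| `nail_tas` | ug/g | toenail total arsenic; LOD when `nail_tas_nd`; empty when missing |
| `nail_tas_nd` | bool | toenail arsenic below the detection limit |
| `ias3`, `ias5`, `mma`, `dma` | ug/L | urinary arsenite, arsenate, MMA, DMA; each holds its LOD (0.5/1/0.5/1) when the paired flag is set |
| `ias3_nd`, `ias5_nd`, `mma_nd`, `dma_nd` | bool | per-species non-detect flags |

In imputed tables every `*_nd` flag is `False` and no cell is empty;
`imputed_cells.csv` records (per imputation `m`) which cells were filled.

## Derived columns (`derived_m*.csv`, added to the cohort columns)

| column | description |
|---|---|
| `tias` | iAs(III) + iAs(V), ug/L |
| `usas` | TiAs + MMA + DMA, ug/L |
| `pct_tias`, `pct_mma`, `pct_dma` | relative levels, percent of USAs (sum to 100) |
| `pmi` | primary methylation index MMA/TiAs |
| `smi` | secondary methylation index DMA/MMA |
| `log10_tias`, `log10_mma`, `log10_dma`, `log10_usas`, `log10_pmi`, `log10_smi` | log10 transforms (dependent variables) |
| `logit_pct_tias`, `logit_pct_mma`, `logit_pct_dma` | logit transforms of the percentages (dependent variables) |
| `tap_water_consumption_recoded` | consumption with 0 recoded to 0.06 L/day |
| `log10_consumption` | log10 of the recoded consumption |
| `log10_water_tas`, `log10_creatinine`, `log10_cotinine`, `log10_bmi`, `log10_age`, `log10_nail_tas` | log10 transforms of predictors |
| `smoking_cat` | 0/1 smoker classification from creatinine-corrected cotinine |
| `female`, `race_other` | indicator recodes of gender and race |

## Model artifacts

* `fits.csv` — per dependent x imputation: `parameter`, `estimate`, `se`,
  `t`, `p_value`, `stars`.
* `pooled_models.csv` — per dependent: pooled `estimate`, `se`, `df`, `t`,
  `p_value`, `within_variance`, `between_variance`, `stars` (combined over
  imputations).
* `selection_tally.csv` — `candidate`, `count` (of stepwise runs selecting
  it), `total_runs`, `retained` (count strictly above threshold),
  `in_final_model`.
* `table1.csv` — `variable`, `statistic` (geometric mean / mean percent),
  per-group values, pooled `p_value`.
* `correlations.csv` — pooled Fisher-z correlations and age trends.
* `percentiles.csv` — 1st/99th percentiles over all imputed datasets.
* `comparison.csv` — per species: cohort and reweighted-reference geometric
  means, their ratio, non-detect percentages, mean LODs.
* `predicted_curves.csv` — model-predicted urinary concentration vs water
  arsenic per source, covariates at cohort means.
* `truth.csv` — generative ground-truth coefficients (synthetic runs).
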