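# arsmet

Analysis tools for urinary arsenic metabolic profiling in drinking-water-
exposed cohorts.

People chronically exposed to inorganic arsenic (iAs) through home tap water
excrete it in urine as arsenite (iAs(III)), arsenate (iAs(V)), and the
methylated metabolites MMA and DMA. How efficiently an individual methylates
iAs — summarised by the primary and secondary methylation indices
PMI = MMA/TiAs and SMI = DMA/MMA, with TiAs = iAs(III)+iAs(V) — modifies the
health risk of exposure, and is itself modified by gender, age, BMI and
smoking. Analysing such cohorts is statistically awkward: many urinary
measurements fall below analytical detection limits (LODs), some records are
missing, and the dose–response in water arsenic is non-linear at low doses.

`arsmet` implements the full inferential chain for this setting:

* **Left-censored log-normal (Tobit) regression** on log10 concentrations
  (`arsmet.censored`), the basis for **proper multiple imputation** of
  non-detects and missing values (`arsmet.imputation`): censored cells are
  drawn from the fitted conditional distribution truncated above at the LOD,
  with model parameters redrawn before each of the M = 20 completed datasets.
* **Derived variables** (`arsmet.derived`): TiAs, USAs = TiAs+MMA+DMA,
  relative levels %TiAs/%MMA/%DMA, PMI, SMI, log10/logit transforms, the
  0 → 0.06 L/day water-consumption recode, a cotinine-based smoking
  classification, and the cigarette aggregate-exposure arithmetic.
* **Bivariate analyses pooled over imputations** (`arsmet.bivariate`):
  geometric means and mean percentages by group, Fisher-z correlations, age
  trends, percentile ranges.
* **Stepwise predictor selection across imputations** (`arsmet.selection`):
  bidirectional stepwise runs over all dependent × imputation combinations
  with a strict more-than-25-of-180 retention rule and post-hoc revision
  into the final model structure.
* **The non-linear offset dose–response model** (`arsmet.model`): for each
  transformed biomarker Y,

      Y = α_DWS + β_DWS · log10(10^α_LogOffset + WaterAs)
        + β_Q·log10(Q) + β_C·log10(Creatinine) + β_F·Female
        + β_B·log10(BMI) + β_A·log10(Age) + β_S·log10(Cotinine) + β_R·Fish

  with separate intercepts and slopes per drinking-water source (untreated,
  filtered, other treatment, bottled) and an estimated positive water-arsenic
  offset 10^α_LogOffset; fitted by profiled non-linear least squares.
* **Combining rules for multiple imputation** (`arsmet.pooling`): pooled
  estimates, within/between-imputation variances, degrees of freedom and
  p-values.
* **Survey comparison** (`arsmet.survey`): censored weighted geometric
  means, post-stratification of a reference survey to the cohort's
  gender × race × age-band distribution, and per-species GM ratio tables.
* **Synthetic cohort generator with known ground truth**
  (`arsmet.simulate`), so the whole chain is testable without any
  restricted data, plus a seeded pipeline and CLI (`arsmet.pipeline`,
  `arsmet all`).

The two fit-shaped cores follow scikit-learn estimator conventions
(`CensoredLogNormalRegression`, `CohortImputer`, `OffsetDoseResponseModel`
with `fit`/`predict`/`transform`, `get_params`, and fitted `*_` attributes).

## Worked example

```python
from arsmet import (CohortConfig, impute_nondetects, fit_offset_model,
                    rubin_pool)
from arsmet.simulate import generate_cohort_frame
from arsmet.derived import add_derived_columns

cohort = generate_cohort_frame(CohortConfig(), seed=5)   # 904 participants
print(f"iAs(V) non-detects: {100 * cohort.ias5_nd.mean():.0f}%")

sets = impute_nondetects(cohort, m=20, seed=1)
fits = [fit_offset_model(add_derived_columns(s.frame), "log10_dma")
        for s in sets]
i = fits[0].params.parameter_names().index("slope_untreated")
pooled = rubin_pool([f.estimates[i] for f in fits],
                    [f.se[i] ** 2 for f in fits])
print(f"untreated-tap slope: {pooled.estimate:.3f} (SE {pooled.se:.3f}), "
      f"p = {pooled.p_value:.2e}")
```

Output:

```
iAs(V) non-detects: 69%
untreated-tap slope: 0.711 (SE 0.083), p = 1.14e-17
```

69 % of simulated arsenate values fall below its 1 µg/L LOD, so a large
share of the analysis data is imputed; the pooled dose slope for log10 DMA
on the offset-log water-arsenic scale lands within one standard error of the
generative truth of 0.776, with an SE that includes between-imputation
variance.

A complete seeded run writing cohort, imputed datasets, bivariate tables,
selection tally, per-imputation fits, pooled model reports, survey
comparison and prediction curves:

```bash
arsmet --seed 1 --outdir run1 all
```

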