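# Methods

## Setting and model

The package analyses cohorts of older adults (enrollment minimum 45 years)
whose home tap water carries total arsenic (TAs) from below the 3 µg/L
detection limit up to 1850 µg/L. Each participant contributes urinary
arsenite, arsenate, MMA and DMA concentrations (µg/L, LODs 0.5/1/0.5/1),
toenail total arsenic, urinary cotinine and creatinine, and questionnaire
covariates. Nine dependent variables are modelled: log10 of TiAs, MMA, DMA
and USAs; logit of %TiAs, %MMA, %DMA; and log10 of PMI and SMI.

The dose–response model for a transformed biomarker Y is

    Y = α_DWS + β_DWS · log10(10^α_LogOffset + WaterAs)
      + β_Q·log10(Q) + β_C·log10(C) + β_F·F + β_B·log10(BMI)
      + β_A·log10(Age) + β_S·log10(S) + β_R·R + ε,

with separate intercept α_DWS and slope β_DWS for each of four
drinking-water-source categories (untreated tap, filtered tap, other
treatment, bottled). The offset 10^α_LogOffset (µg/L) keeps the dose term
finite and monotone at zero water arsenic; it can be read as background
arsenic intake from unmeasured sources, and supersedes a quadratic-in-log
water term. It is parameterised on the log10 scale so it stays positive
during optimisation. For the relative-level and index outcomes the offset
is hard to identify and contributes nothing (the dose slopes are null
there), so those models drop it and use plain log10(WaterAs) on completed,
strictly positive water values.

Concentrations are never creatinine- or specific-gravity-corrected;
creatinine enters only as a covariate. Zero reported tap-water consumption
is recoded to 0.06 L/day (a quarter cup) before the log transform.
Percentages are clipped to [0.1 %, 99.9 %] before the logit so completed
datasets with degenerate compositions stay finite.

## Censored imputation

Analyte concentrations are treated as log-normal; non-detects are draws
from the lower tail below the LOD. Each analyte's location is modelled by
left-censored (Tobit-type) maximum likelihood on log10 values with
covariates; with no censoring this coincides with OLS. The imputer is
*proper*: before each of the M = 20 completed datasets, the coefficient
vector and residual SD are redrawn from their asymptotic distribution
(observed-information covariance), so between-imputation variance carries
estimation uncertainty. Censored cells are then drawn from the conditional
normal truncated above at the log10 LOD by inverse-CDF sampling, which
guarantees imputed values strictly inside (0, LOD).

The conditional ordering — water TAs (intercept-only), missing covariates
(log-normal), then DMA → MMA → iAs(III) → iAs(V) → nails, each conditioned
on log10 water, gender, log10 age, log10 BMI, source category, log10
creatinine, and the already-completed analytes — is a design choice; the
sequence runs from least to most censored so that each heavily censored
analyte borrows strength from better-observed siblings, which is what
preserves cross-analyte correlations (verified to within 0.1 of the
pre-censoring correlation at n = 2000).

## Estimation of the offset model

For a fixed α_LogOffset the model is linear in all other parameters, so the
fit profiles the offset: inner linear least squares at each candidate
offset, an outer bounded 1-d minimisation over α_LogOffset ∈ [−3, 3.5]
seeded by a multi-start grid (including −1, 0, 0.5, 1, 1.5), then a
Levenberg–Marquardt polish of the full 16-parameter vector with the
analytic Jacobian (∂dose/∂α = 10^α/(10^α + w)). Convergence tolerances are
1e-10 on relative SSE change; the asymptotic covariance is the Gauss–Newton
approximation σ²(JᵀJ)⁻¹ at the optimum. On noise-free data the truth is
recovered to machine precision; with the offset disabled the fit equals the
OLS oracle exactly. The profiled SSE is empirically unimodal near the
optimum (checked on a grid), which is why a single polished profile
optimum suffices.

## Pooling

Per-imputation estimates q_i with squared SEs u_i combine as
q̄ = mean(q), W = mean(u), B = var(q), T = W + (1+1/M)B, with classic
large-sample degrees of freedom ν = (M−1)(1 + W/((1+1/M)B))²; B = 0 falls
back to the normal reference. The small-sample Barnard–Rubin correction is
not applied (switchable in principle; the cohort n of ~900 makes the
difference negligible). Correlations pool on the Fisher-z scale with
variance 1/(n−3); two-group tests pool the mean difference of transformed
values with pooled-variance SEs.

## Stepwise selection

For all dependent × imputation combinations (9 × 20 = 180 by default) a
bidirectional stepwise linear selection runs over the candidate roster
(gender, race, BMI, age, creatinine, smoking category, cotinine, recent
alcohol, recent fish, water TAs linear + quadratic, source category, daily
consumption, source × TAs interaction). Interactions and the quadratic term
are eligible only when their main effects are in the model; perfectly
collinear additions are skipped; singular runs are dropped with a warning
and shrink the effective total. A candidate selected in strictly more than
25 of 180 runs is retained.

The default entry/removal criterion is Schwarz-criterion (BIC) improvement,
mirroring the default criterion of the standard stepwise selection
procedure in the major statistical packages; a classical p-value mode
(entry/stay 0.15) is available as configuration. The BIC default is also
what makes the retention rule well calibrated: simulation under a global
null shows p-value-0.15 stepwise admits each null candidate in roughly 15 %
of runs — expected tallies near 27/180, above the retention threshold —
whereas BIC keeps null tallies far below it (every candidate stays under
the threshold in well over 90 % of null tallies at n = 904).

Post-hoc revision of the retained set: cotinine supersedes the categorical
smoking variable; any selected water-related terms are replaced by the
water-source × transformed-TAs structure (per-source intercepts and
slopes); the recent fish/shellfish indicator is forced in on prior
substantive grounds even though it is rarely selected.

## Survey comparison

Reference-survey geometric means use a weighted left-censored log-normal
likelihood (equivalent to a log-normal survival fit on the log scale).
Reference weights are post-stratified over gender × race × age-band cells
(40–49, 50–59, 60–69, 70–79, 80+) so weighted cell shares match the
cohort's distribution while conserving total weight; empty reference cells
with positive target share are an error. Comparison tables report
per-species GM ratios, non-detect percentages and mean detection limits on
both sides. No design-based variance (strata/PSU) estimation is attempted.

## Synthetic cohort generator

The generator is the package's definition of the study conditions. It
draws covariates (59 % female; ages 45 + 47·Beta(1.8, 3.2), median ≈ 61;
90 % white; log-normal BMI with median ≈ 28.4; 16 % smokers with bimodal
log-normal cotinine; log-normal creatinine; 29 % recent fish; four source
categories; truncated log-normal water TAs on (0, 1850]; zero consumption
with probability 93/904 to exercise the recode), computes expected log10
TiAs, MMA and DMA from per-species truth coefficient sets through the model
equation above, adds correlated Gaussian residuals (correlation 0.6),
splits TiAs into iAs(III)/iAs(V) with a Beta(7, 3) fraction, generates
toenail arsenic from water arsenic, and finally applies censoring at the
configured LODs and missingness (toenails 59/904; cotinine, creatinine and
BMI 1/904 each).

The default truth takes the published final-model slopes and covariate
coefficients for TiAs, MMA and DMA. The per-source intercepts are shifted
per species (−0.279, −0.340, −0.733) and the residual SDs set to
(0.45, 0.35, 0.30): reported intercepts are conditional on the source
cohort's unavailable covariate joint, so they are re-anchored once, by
Monte-Carlo calibration against the cohort's published summary statistics,
to the package's own covariate distributions. No single log-normal joint
can reproduce the reported non-detect rates (32/64/24/5 %) and the reported
percentile spreads of the indices simultaneously — the implied
MMA–DMA correlation exceeds 1 — so the defaults favour correct ordering and
realistic magnitudes (defaults give roughly 22/70/10/9 % non-detects and
geometric means near 3/2/4 µg/L). What passing tests show is therefore
structural correctness of the chain (censoring handled, correlations
preserved, truth recovered, CIs calibrated), not distributional fidelity to
any particular cohort.

USAs, the percentages and the indices are derived sums/ratios, so their
log/logit transforms do not follow the model equation exactly under this
generator; coefficient-recovery and CI-coverage studies therefore target a
directly generated species (DMA), for which an exact truth exists.

## Validation studies and problem sizes

* CI coverage: 100 replicate cohorts at n = 904, M = 5 imputations
  (a deliberately reduced M; coverage is insensitive to M beyond ~5),
  dependent log10 DMA, parameter β_DWS (untreated); pooled 95 % CIs cover
  truth in 90–99 % of replicates.
* Retention-rule calibration: 100 null tallies, each a full 9 × 20 stepwise
  grid at n = 904.
* Imputed-tail moment: mean imputed below-LOD DMA vs E[X | X < LOD] by
  quadrature at n = 2000, within 3 Monte-Carlo SEs.
* Oracle agreements: pooling vs a brute-force implementation (1e-12);
  censored MLE vs an independent survival-package fit; offset-free fit vs
  OLS (1e-8); noiseless recovery (1e-6).

## Known limitations

* The generator reproduces structural features (LODs, missingness ranges,
  covariate roles), not the joint distribution of any real cohort; absolute
  bivariate results on default synthetic data are not comparable to any
  published cohort table.
* The imputation conditional structure is one reasonable choice; the
  original analysis's exact conditioning is unknown.
* Stepwise "default criteria" differ across software; equivalence with any
  specific proprietary implementation is not claimed.
* The survey comparison reports point ratios only; no variance for the
  ratios is computed.
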