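# Methods

This note documents the statistical model behind `carriermr`, the defaults
it ships with, the synthetic data the tests run on, and the numerical
decisions taken where the design was genuinely open.

## The estimation problem

Clinic-based *BRCA1/2* carrier cohorts are not population samples: families
enter because someone was affected, so cases are over-represented and
relatives share genotypes and risk. Three features of the analysis address
this:

1. **Kin-cohort weighting.** Within strata of gene × 5-year exit-age band,
   cases receive weight p_exp/p_obs and non-cases (1−p_exp)/(1−p_obs),
   where p_obs is the observed case fraction in the stratum and p_exp the
   expected fraction from external incidence in carriers. The weighted
   case fraction then equals p_exp exactly, and because the weights are
   proportional to inverse sampling probabilities under outcome-dependent
   sampling, the weighted partial likelihood removes the ascertainment bias
   that attenuates the unweighted fit (the suite demonstrates both halves:
   weighted recovery within Monte-Carlo error, unweighted bias many SEs
   wide at strong oversampling).
2. **Family-clustered sandwich variance.** Score residuals of the weighted
   partial likelihood are summed within families before the outer product;
   the fitter reproduces R `survival::coxph(..., weights, cluster)` to
   1e-8 on coefficient, naive SE, robust SE and log-likelihood for both
   ties methods (values frozen in `tests/test_cox.py`).
3. **Age as timescale with episode splitting.** Persons enter at birth and
   exit at the first of ovarian-cancer diagnosis, breast-cancer diagnosis,
   RRSO, death, or end of follow-up; only ovarian cancer is an event.
   Menopause splits a person into premenopausal and postmenopausal
   episodes; splitting preserves total follow-up time and event counts
   exactly. Missing menopause age is imputed at 50 (configurable; 46 is
   the shipped sensitivity alternative).

### Incidence-table semantics

The external incidence input is stored as the expected case fraction among
carriers whose follow-up *ends* in an age band (per gene). This is the
quantity the weighting contract needs — the weighted case fraction within
an exit-age stratum must equal it — and it is what
`simulate.reference_incidence` measures on an unascertained reference
cohort. It approximates, but is not identical to, the conditional
probability of a first event within the band; with 5-year bands the
difference is absorbed into p_exp itself because the same definition is
used on both sides of the weight.

## Genetic scores

Raw score = Σ β_XGi · dosage_i with external per-allele weights; variants
with imputation quality < 0.5 are excluded at load time (quality exactly
0.5 is retained). Missing person-variant dosages are mean-imputed as
2·EAF. Allele alignment accepts exact, swapped, and strand-complement
matches and rejects palindromic A/T / C/G variants only when the effect
allele frequency is in [0.4, 0.6], where strand cannot be resolved.
Scaling to trait units is trait-on-score OLS among non-case carriers of
both genes pooled (the reported intercept of ~165 cm for height fixes the
regression direction); BMI scales to BMI at questionnaire, never to early
adulthood BMI.

## MR estimators

The IVW estimator and its SE follow the fixed-effect inverse-variance
formulas (equivalently an SE⁻²-weighted through-origin regression of
β_YG on β_XG; the suite checks both routes agree to 1e-10). Heterogeneity
uses Cochran Q on the per-variant Wald ratios β_YG/β_XG with first-order
SEs SE(β_YG)/|β_XG|, under which the IVW mean of the ratios equals the IVW
slope; I² = max(0, (Q−k+1)/Q). MR-Egger is an SE⁻²-weighted regression
with a free intercept after orienting all β_XG ≥ 0; its SEs use the
multiplicative random-effects convention (inflated by max(1, σ̂), never
deflated) and the intercept test refers to t with k−2 df. Variants whose
per-variant Cox fit fails (constant dosage, separation) are flagged,
excluded from every combination, and enumerated in the per-variant table.
Instruments are treated as uncorrelated (no LD adjustment), matching the
independence assumption of the formulas.

## Two-stage residual inclusion

Stage 1 is OLS of the measured trait on the scaled score plus the
adjustment set (8 PCs, birth-cohort decade, country, gene), fitted on all
persons with a measured trait; instrument strength is reported as the
squared t of the score. Stage 2 is the weighted Cox model on the trait,
the covariates, and the stage-1 residual; if the residual is numerically
zero (trait an exact function of the score) it is dropped and stage 2
reduces to the plain Cox fit. Uncertainty comes from a percentile
bootstrap that resamples whole families with replacement (replicate copies
of a family count as distinct clusters); individual-level resampling is
available by flag. Inverted-CDF quantiles make the B = 2 CI the ordered
replicate pair. Bootstrap replicates run on pre-built design arrays with
the dummy coding frozen from the full sample, so every replicate uses the
same columns; a test verifies one fast-path replicate equals an explicit
refit on the same resampled families. Whether the kin-cohort weights enter
stage 2 is switchable; the pipeline default uses them, consistent with
every other outcome model.

## The synthetic cohort generator

`simulate.simulate_cohort` emulates the statistical structure the analysis
assumes:

* **Families** of full sisters (sizes 1–4, P = 0.55/0.25/0.12/0.08);
  genotypes by parental transmission from two unobserved founders, giving
  sibling dosage correlation 0.5 and family-clustered events.
* **Instrument panel**: EAFs uniform on (0.05, 0.95), half-normal
  trait-increasing per-allele effects.
* **Trait**: mean 164.8, SD 6.9 cm for height (25.2, 5.1 kg/m² for BMI),
  score-to-trait slope derived as λ = SD·√(R²/Var(GS)) so the population
  R² of trait on score hits the target (0.13 height, 0.03 BMI); a single
  standard-normal confounder can load on both trait and log-hazard.
* **Events**: Weibull proportional hazards per gene (shape 4.5; scale
  92.9 / 119.8 years, i.e. lifetime risk by 80 of ≈40% for BRCA1 and ≈15%
  for BRCA2 — order-of-magnitude realism only), log HR linear in the trait
  and confounder. Competing censoring: end of follow-up truncated-normal
  (52, 13) on [22, 90]; RRSO in 18% at (44, 6) on [30, 60]; constant
  breast-cancer (0.004/yr) and death (0.002/yr) hazards from age 18.
  Menopause truncated-normal (48, 4) on [35, 60], 20% missing.
* **Measured anthropometry** missing for 66% of persons, mirroring the
  roughly one-third measurement availability of the real cohort.
* **Ascertainment**: families containing a case are kept with probability
  min(1, factor·base), case-free families with probability base
  (default 0.3). The oversampling factor is a free simulation knob — the
  real recruitment mechanism is not quantified anywhere — so the
  weight-recovery property is demonstrated across factors rather than at a
  calibrated value.

What the generator does **not** emulate: linkage disequilibrium between
instruments, population stratification beyond synthetic PC columns,
pedigrees deeper than sibships, secular trends in incidence, or
menopause-dependent causal effects. Passing tests therefore show that the
estimators are correct under the stated sampling and hazard model, not
that any particular real-data estimate is right.

## Numerical choices

* **Cox fitting**: Newton–Raphson on covariates centred and scaled to unit
  SD (coefficients mapped back), step-halving with an ∞-norm trust region
  of 10 on the standardized scale, convergence when the step falls below
  1e-10. Efron ties by default (Breslow by flag); tied event times expand
  into Efron steps so the untied case is the d = 1 special case.
* **Failure modes**: constant or collinear designs are rejected up front
  (SVD condition check, gesvd driver); monotone likelihood is reported as
  a convergence failure once a standardized coefficient passes 30.
  Categorical covariate levels with zero events are merged into the modal
  level before coding (logged), since their dummies have no finite MLE.
* **Weight strata**: gene × 5-year exit-age bands; bands with fewer than
  10 persons or a degenerate observed case fraction merge into the next
  band upward, and the merge is logged.
* **Subgroup heterogeneity** (histology, grade, gene): two-sample Wald
  test on the difference of class coefficients with robust SEs, treating
  classes as independent; cases of the complementary class are censored at
  diagnosis age. Menopausal-status subgroup estimates come from the pre-
  and postmenopausal episode subsets, and the interaction p is the Wald p
  of the score × postmenopausal product term — with a time-varying
  modifier this doubles as a proportional-hazards test.
* **p-values** are clamped to the smallest positive double so the (0, 1]
  contract survives underflow.

## Problem sizes in the shipped tests

The statistical acceptance checks run at: n ≈ 20,000 persons for
ascertainment-weight recovery (78,000 base families, oversampling factor
12) and for confounded causal recovery (12,000 families, 50 variants,
confounder loading 3.0 cm / 0.4 log-hazard); 500 null replicates of
n = 2,000 for interaction-test calibration; and 100 outer cohorts
(~430 persons each, follow-up extended to mean age 65 so each carries
~40–60 events) × B = 500 bootstrap replicates for CI coverage. The
bootstrap B is a scaled-down stand-in for the 10,000 replicates one would
use on a real analysis; coverage at these sizes sits at the conservative
edge (≈0.99) because percentile intervals over-cover with few events per
cohort.

## Known limitations

* The weighting corrects sampling that depends on case status within a
  stratum; family-level ascertainment induces a second-order dependence
  through relatives' outcomes that the weights do not model. Empirically
  the residual bias is well inside Monte-Carlo error at the tested
  oversampling strengths.
* Robust SEs for the per-class heterogeneity test ignore the covariance
  induced by shared non-cases across class fits.
* MR-Egger power is limited at small instrument panels; the intercept test
  is reported, not gated on.
* The TSRI stage-2 naive SE ignores stage-1 uncertainty by construction;
  the bootstrap CI is the supported uncertainty statement.
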