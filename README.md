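# carriermr

Mendelian-randomisation analysis of quantitative anthropometric traits
(height, body-mass index) against a time-to-event cancer outcome in
clinic-ascertained *BRCA1*/*BRCA2* mutation-carrier cohorts — implemented as
a tested, reusable pipeline driven by a synthetic-cohort generator, so every
stage can be exercised without access to restricted consortium data.

## Who this is for

Genetic epidemiologists who want to (a) study how the kin-cohort weighted
Cox design behaves under family-based ascertainment, (b) prototype MR
analyses with survival outcomes, or (c) reuse the individual components:
a weighted counting-process Cox fitter with family-clustered sandwich
variance, polygenic-score scaling, IVW/MR-Egger estimators, and two-stage
residual inclusion with a family bootstrap.

## The model

**Genetic score.** With per-allele GWAS effects *β*<sub>XGi</sub> and
effect-allele dosages SNP<sub>i</sub> ∈ [0, 2],
GS = Σᵢ *β*<sub>XGi</sub> SNP<sub>i</sub>. The raw score is rescaled to trait
units by OLS of the measured trait on the score among non-case carriers
(scaled = *β*₀ + *β*₁·GS).

**Weighted Cox model.** Ovarian-cancer risk is modelled on the age
timescale; persons are censored at breast-cancer diagnosis, risk-reducing
salpingo-oophorectomy (RRSO), death, or end of follow-up, whichever comes
first. Menopausal status is a time-varying covariate (premenopausal from
birth until natural menopause or RRSO; missing ages imputed at 50).
Because affected families are oversampled into clinic cohorts, cases and
non-cases are weighted within gene × exit-age strata so the weighted case
fraction matches external incidence: case weight p_exp/p_obs, non-case
weight (1−p_exp)/(1−p_obs). Variances use a robust sandwich aggregating
score residuals within families.

**IVW estimator.** Per-variant log hazard ratios *β*<sub>YGi</sub> with
standard errors SE(*β*<sub>YGi</sub>) come from one adjusted weighted Cox
fit per variant; the combined causal effect per trait unit is

    β_YX = Σᵢ β_XGi β_YGi SE(β_YGi)⁻² / Σᵢ β_XGi² SE(β_YGi)⁻²
    SE_YX = (Σᵢ β_XGi² SE(β_YGi)⁻²)^(−1/2)

with Cochran Q / I² on the per-variant Wald ratios and MR-Egger regression
(free intercept, instrument effects oriented positive) as the pleiotropy
check.

**TSRI.** Stage 1: OLS of the measured trait on the scaled score plus
covariates. Stage 2: weighted Cox on the trait, covariates, and the stage-1
residual; the trait coefficient is the causal log HR per trait unit, with a
percentile CI from resampling whole families with replacement.

## Worked example

```python
from carriermr.pipeline import RunConfig, run_pipeline

cfg = RunConfig(trait="height", seed=7, outdir="demo",
                simulate={"n_families": 2000, "n_snps": 60,
                          "causal_log_hr_per_unit": 0.002,
                          "case_oversampling_factor": 3.0},
                bootstrap_b=200)
res = run_pipeline(cfg)
print(res["ladder"][["model", "n_events", "hr", "ci_lo", "ci_hi", "p"]])
```

prints the sequential-adjustment ladder for the height score (HR per 10 cm
of genetically predicted height):

```
               model  n_events    hr  ci_lo  ci_hi     p
principal components       185 1.245  0.676  2.291 0.482
           + country       185 1.183  0.638  2.192 0.594
      + birth cohort       185 1.174  0.630  2.188 0.612
   + mutation status       185 1.178  0.636  2.182 0.603
 + menopausal status       185 1.177  0.636  2.180 0.603
```

and the remaining artifacts report, for the same run,

```
scaling: beta0=140.952 beta1=11.258 r2=0.1466 n=365
IVW:  HR per 10 cm = 1.165 (0.627-2.166), I2 = 0.0%, Egger intercept p = 0.21
TSRI: HR per 10 cm = 1.703 (0.366-14.617), stage-1 F = 72
interaction p (menopause): 0.792
```

Reading this: the score explains ~14.7% of height variance in this
synthetic cohort (non-case carriers, n = 365 with measured height); the
generating causal effect was HR ≈ 1.02 per 10 cm, and all three estimators
cover it — the wide CIs at ~185 events are exactly why the headline MR
estimates in carrier cohorts of this kind are imprecise. The simulated
truth for every run sits in the cohort's `truth` record.

The same analysis runs from the shell:

```bash
carriermr simulate --outdir data --seed 7 --n-families 2000 --oversample 3
carriermr validate --phenotypes data/phenotypes.tsv --dosages data/dosages.tsv \
    --snp-weights data/snp_weights.tsv --incidence data/incidence.tsv
carriermr run --config config.yaml
carriermr report --outdir results
```

## Layout

| module | contents |
|---|---|
| `carriermr.simulate` | seeded family-structured cohort generator + ascertainment |
| `carriermr.score` | weight-panel loading, allele alignment, GS construction, scaling |
| `carriermr.cox` | weighted counting-process Cox engine (Efron/Breslow, cluster sandwich) |
| `carriermr.survival` | kin-cohort weights, episode splitting, subgroup/subtype fits |
| `carriermr.mr` | per-variant scan, IVW, Cochran Q / I², MR-Egger, rescaling |
| `carriermr.tsri` | two-stage residual inclusion + family bootstrap |
| `carriermr.pipeline` / `carriermr.cli` | configuration-driven orchestration, `carriermr` entry point |

See `docs/methods.md` for modelling assumptions, parameter defaults, and
numerical choices.
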