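"""Seeded synthetic BRCA1/2 carrier cohorts.

The generator emulates the statistical structure the analysis assumes so the
whole pipeline is testable without consortium data:

* families of full sisters with genotypes built by parental haplotype
  transmission (two unobserved founders per family), giving within-family
  dosage correlation ~0.5 and hence within-family event clustering;
* a quantitative trait (height- or BMI-like) driven by a weighted allele
  score plus a single standard-normal confounder and Gaussian noise, with the
  score-to-trait slope calibrated so the population R^2 of trait on score
  hits a target;
* ovarian-cancer onset from a Weibull proportional-hazards model per gene
  (log HR linear in the trait and the confounder), with competing censoring
  by breast cancer, risk-reducing salpingo-oophorectomy (RRSO), death and end
  of follow-up;
* clinic-style ascertainment that oversamples families containing a case;
* missingness of measured anthropometry for a configurable fraction.

All randomness flows through one ``numpy.random.Generator`` created from the
config seed; the same config therefore reproduces the cohort exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GENES = ("BRCA1", "BRCA2")
COUNTRIES = ("USA", "UK", "NL", "DE", "FR", "AU")
HISTOLOGIES = ("serous", "mucinous", "endometrioid", "clear cell", "other")
HISTOLOGY_P = (0.679, 0.015, 0.107, 0.013, 0.186)
GRADES = ("well", "moderate", "poor/undiff")
GRADE_P = (0.046, 0.210, 0.744)


class SimulationError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass
class SimConfig:
    """Parameters of one synthetic carrier cohort.

    Defaults are the height-like study conditions: trait mean/SD matching
    non-case carriers (164.8 cm, 6.9 cm) and a score explaining ~13% of trait
    variance; use :func:`bmi_config` for the BMI-like conditions.
    """

    n_families: int = 4000
    family_size_dist: tuple = (0.55, 0.25, 0.12, 0.08)  # P(size = 1..k)
    n_snps: int = 120
    eaf_range: tuple = (0.05, 0.95)
    beta_xg_scale: float = 0.05          # half-normal scale, score units/allele
    trait_mean: float = 164.8
    trait_sd: float = 6.9
    gs_r2_target: float = 0.13
    causal_log_hr_per_unit: float = 0.0  # log HR per trait unit
    baseline_hazard: dict = field(
        default_factory=lambda: {
            # Weibull (shape, scale): lifetime risk by 80 ~ 40% / 15%
            "BRCA1": (4.5, 92.9),
            "BRCA2": (4.5, 119.8),
        }
    )
    confounder_effect: tuple = (0.0, 0.0)  # (trait units, log-hazard units)
    menopause_age_dist: tuple = (48.0, 4.0, 35.0, 60.0)  # trunc-normal
    censoring_age_dist: tuple = (52.0, 13.0, 22.0, 90.0)  # end of follow-up
    case_oversampling_factor: float = 1.0
    missing_trait_fraction: float = 0.66
    seed: int = 0
    # plumbing beyond the core statistical knobs
    frac_brca1: float = 0.65
    rrso_prob: float = 0.18
    rrso_age_dist: tuple = (44.0, 6.0, 30.0, 60.0)
    breast_hazard: float = 0.004         # competing censoring, per year
    death_hazard: float = 0.002
    menopause_missing_frac: float = 0.2
    base_family_rate: float = 0.3        # non-case family sampling rate

    def validate(self) -> None:
        if self.n_snps < 1:
            raise SimulationError("n_snps must be >= 1")
        if self.n_families < 1:
            raise SimulationError("n_families must be >= 1")
        lo, hi = self.eaf_range
        if not (0 < lo < hi < 1):
            raise SimulationError("eaf_range must be inside (0, 1)")
        if not 0 <= self.gs_r2_target < 1:
            raise SimulationError("gs_r2_target must be in [0, 1)")
        for name in ("missing_trait_fraction", "menopause_missing_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimulationError(f"{name} out of range: {v}")
        if self.trait_sd <= 0 or self.beta_xg_scale <= 0:
            raise SimulationError("scale parameters must be positive")
        if self.case_oversampling_factor < 1:
            raise SimulationError("case_oversampling_factor must be >= 1")
        if abs(sum(self.family_size_dist) - 1) > 1e-9:
            raise SimulationError("family_size_dist must sum to 1")


def bmi_config(**overrides) -> SimConfig:
    """BMI-like study conditions: mean 25.2 kg/m^2, SD 5.1, R^2 target 0.03."""
    cfg = SimConfig(
        n_snps=60,
        trait_mean=25.2,
        trait_sd=5.1,
        gs_r2_target=0.03,
        beta_xg_scale=0.04,
    )
    return dataclasses.replace(cfg, **overrides)


@dataclass
class SyntheticCohort:
    """A simulated carrier cohort plus the generating truth.

    ``phenotypes`` is one row per person; ``dosages`` is persons x SNPs in
    [0, 2] counting the trait-increasing (effect) allele; ``snp_weights`` is
    the instrument panel in the SNP-weight TSV layout. ``truth`` records
    every generating parameter needed to score recovery; ``latent`` carries
    per-person latent quantities (uncensored onset age, true trait,
    confounder) used only by tests.
    """

    phenotypes: pd.DataFrame
    dosages: pd.DataFrame
    snp_weights: pd.DataFrame
    truth: dict
    latent: pd.DataFrame

    def write(self, outdir) -> dict:
        """Write the three analysis input TSVs plus the truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "phenotypes": outdir / "phenotypes.tsv",
            "dosages": outdir / "dosages.tsv",
            "snp_weights": outdir / "snp_weights.tsv",
            "truth": outdir / "truth.json",
        }
        self.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False,
                               float_format="%.6g")
        self.dosages.to_csv(paths["dosages"], sep="\t", index=True,
                            float_format="%g")
        self.snp_weights.to_csv(paths["snp_weights"], sep="\t", index=False,
                                float_format="%.8g")
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
        return paths


def _truncnorm(rng, mean, sd, lo, hi, size):
    """Truncated normal by rejection (bounds are loose in practice)."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _transmit(rng, parent_alleles, fam_of_person):
    """One transmitted allele per person from a parent's two haplotypes."""
    pick = rng.integers(0, 2, size=(fam_of_person.size, parent_alleles.shape[2]))
    a = parent_alleles[fam_of_person]
    return np.take_along_axis(a, pick[:, None, :], axis=1)[:, 0, :]


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate one cohort under ``config`` (see module docstring)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    sizes = rng.choice(
        np.arange(1, len(config.family_size_dist) + 1),
        size=config.n_families,
        p=np.asarray(config.family_size_dist, dtype=float),
    )
    n = int(sizes.sum())
    fam = np.repeat(np.arange(config.n_families), sizes)

    # instrument panel
    eaf = rng.uniform(*config.eaf_range, size=config.n_snps)
    beta = np.abs(rng.normal(0.0, config.beta_xg_scale, size=config.n_snps))
    beta = np.maximum(beta, 1e-4)  # effect alleles are trait-increasing
    rsids = np.array([f"rs{900000 + i}" for i in range(config.n_snps)])
    bases = np.array(list("ACGT"))
    ea = bases[rng.integers(0, 4, config.n_snps)]
    oa = np.array([bases[bases != a][rng.integers(0, 3)] for a in ea])
    weights_df = pd.DataFrame(
        {
            "rsid": rsids,
            "chrom": rng.integers(1, 23, config.n_snps).astype(str),
            "pos": rng.integers(10_000, 200_000_000, config.n_snps),
            "effect_allele": ea,
            "other_allele": oa,
            "beta": beta,
            "eaf": eaf,
            "info": np.round(rng.uniform(0.6, 1.0, config.n_snps), 3),
        }
    )

    # genotypes: two founders per family, cohort members are sibs
    mother = rng.binomial(1, eaf, size=(config.n_families, 2, config.n_snps))
    father = rng.binomial(1, eaf, size=(config.n_families, 2, config.n_snps))
    dos = (_transmit(rng, mother, fam) + _transmit(rng, father, fam)).astype(float)

    # trait: slope calibrated so population R^2(trait ~ raw score) = target
    raw = dos @ beta
    var_gs = float(np.sum(2 * eaf * (1 - eaf) * beta**2))
    if var_gs <= 0:
        raise SimulationError("instrument panel has zero score variance")
    lam = config.trait_sd * np.sqrt(config.gs_r2_target / var_gs)
    a_trait, a_haz = config.confounder_effect
    resid_var = config.trait_sd**2 * (1 - config.gs_r2_target) - a_trait**2
    if resid_var < 0:
        raise SimulationError(
            "infeasible gs_r2_target/confounder_effect: residual trait "
            f"variance would be {resid_var:.3g}"
        )
    conf = rng.normal(size=n)
    mu_gs = float(2 * eaf @ beta)
    trait = (
        config.trait_mean
        + lam * (raw - mu_gs)
        + a_trait * conf
        + rng.normal(0.0, np.sqrt(resid_var), size=n)
    )

    # event times: Weibull proportional hazards per gene
    gene = np.where(rng.uniform(size=n) < config.frac_brca1, "BRCA1", "BRCA2")
    shape = np.empty(n)
    scale = np.empty(n)
    for g, (sh, sc) in config.baseline_hazard.items():
        m = gene == g
        shape[m], scale[m] = sh, sc
    eta = config.causal_log_hr_per_unit * (trait - config.trait_mean) + a_haz * conf
    onset = scale * (rng.exponential(size=n) / np.exp(eta)) ** (1.0 / shape)

    # competing censoring
    end_fu = _truncnorm(rng, *config.censoring_age_dist, n)
    rrso_age = np.where(
        rng.uniform(size=n) < config.rrso_prob,
        _truncnorm(rng, *config.rrso_age_dist, n),
        np.inf,
    )
    breast = 18.0 + rng.exponential(1.0 / config.breast_hazard, size=n)
    death = 18.0 + rng.exponential(1.0 / config.death_hazard, size=n)
    exits = np.column_stack([onset, breast, rrso_age, death, end_fu])
    exit_age = exits.min(axis=1)
    cause = exits.argmin(axis=1)  # 0=ovca 1=breast 2=rrso 3=death 4=end
    case = cause == 0

    menop = _truncnorm(rng, *config.menopause_age_dist, n)
    menop_missing = rng.uniform(size=n) < config.menopause_missing_frac

    pheno = pd.DataFrame(
        {
            "person": np.array([f"P{i:06d}" for i in range(n)]),
            "family": np.array([f"F{f:05d}" for f in fam]),
            "gene": gene,
            "birth_year": rng.integers(1930, 1981, n),
            "country": rng.choice(COUNTRIES, n, p=(0.3, 0.2, 0.15, 0.15, 0.1, 0.1)),
        }
    )
    for j in range(1, 9):
        pheno[f"pc{j}"] = rng.normal(size=n)
    pheno["case"] = case.astype(int)
    pheno["age_ovca"] = np.where(case, exit_age, np.nan)
    pheno["age_breast"] = np.where(cause == 1, exit_age, np.nan)
    pheno["age_rrso"] = np.where(cause == 2, exit_age, np.nan)
    pheno["age_death"] = np.where(cause == 3, exit_age, np.nan)
    pheno["age_end_followup"] = np.where(cause == 4, exit_age, np.nan)
    pheno["age_menopause_natural"] = np.where(menop_missing, np.nan, menop)

    measured = rng.uniform(size=n) >= config.missing_trait_fraction
    height_like = config.trait_mean > 60  # crude: cm scale vs kg/m^2 scale
    if height_like:
        pheno["height_cm"] = np.where(measured, np.round(trait, 1), np.nan)
        bmi = _truncnorm(rng, 25.2, 5.1, 14, 60, n)
        pheno["bmi_now"] = np.where(measured, np.round(bmi, 1), np.nan)
    else:
        pheno["bmi_now"] = np.where(measured, np.round(trait, 2), np.nan)
        h = _truncnorm(rng, 164.8, 6.9, 130, 200, n)
        pheno["height_cm"] = np.where(measured, np.round(h, 1), np.nan)
    pheno["bmi_young"] = np.where(
        measured,
        np.round(0.6 * (pheno["bmi_now"] - 25.2) + 21.3 + rng.normal(0, 1.5, n), 2),
        np.nan,
    )
    pheno["parity"] = np.minimum(rng.poisson(1.8, n), 6)
    pheno["age_menarche"] = np.round(_truncnorm(rng, 13.0, 1.5, 9, 18, n), 1)
    pheno["histology"] = pd.Series(
        rng.choice(HISTOLOGIES, n, p=HISTOLOGY_P), dtype=object
    ).where(case, other=None)
    pheno["grade"] = pd.Series(
        rng.choice(GRADES, n, p=GRADE_P), dtype=object
    ).where(case, other=None)

    dosages = pd.DataFrame(dos, index=pd.Index(pheno["person"].values,
                                               name="person"), columns=rsids)

    truth = {
        "seed": int(config.seed),
        "causal_log_hr_per_unit": float(config.causal_log_hr_per_unit),
        "confounder_effect": [float(a_trait), float(a_haz)],
        "gs_trait_slope": float(lam),
        "gs_r2_target": float(config.gs_r2_target),
        "trait_mean": float(config.trait_mean),
        "trait_sd": float(config.trait_sd),
        "beta_per_allele_score_units": beta.tolist(),
        "beta_per_allele_trait_units": (lam * beta).tolist(),
        "eaf": eaf.tolist(),
        "baseline_hazard": {g: list(map(float, v))
                            for g, v in config.baseline_hazard.items()},
        "n_persons": int(n),
        "n_families": int(config.n_families),
        "base_family_rate": float(config.base_family_rate),
        "trait_column": "height_cm" if height_like else "bmi_now",
    }
    latent = pd.DataFrame(
        {
            "person": pheno["person"].values,
            "onset_age": onset,
            "trait_true": trait,
            "confounder": conf,
            "exit_age": exit_age,
        }
    )
    return SyntheticCohort(pheno, dosages, weights_df, truth, latent)


def ascertain(cohort: SyntheticCohort, factor: float, seed: int,
              base_rate: float | None = None) -> SyntheticCohort:
    """Clinic-style ascertainment: oversample families containing a case.

    Families with at least one ovarian-cancer case are retained with
    probability ``min(1, factor * base_rate)``; case-free families with
    probability ``base_rate``. All members of a retained family are kept, so
    the family structure survives intact.
    """
    if factor < 1:
        raise SimulationError("ascertainment factor must be >= 1")
    pheno = cohort.phenotypes
    if pheno["case"].sum() == 0:
        raise SimulationError("cohort has no cases; cannot ascertain")
    if base_rate is None:
        base_rate = cohort.truth.get("base_family_rate", 0.3)
    rng = np.random.default_rng(seed)
    fam_case = pheno.groupby("family", sort=True)["case"].max()
    p_keep = np.where(fam_case.values > 0, min(1.0, factor * base_rate), base_rate)
    kept = fam_case.index[rng.uniform(size=fam_case.size) < p_keep]
    mask = pheno["family"].isin(kept).values
    new_pheno = pheno.loc[mask].reset_index(drop=True)
    persons = new_pheno["person"].values
    truth = dict(cohort.truth)
    truth["ascertainment"] = {"factor": float(factor), "base_rate": float(base_rate)}
    truth["n_persons"] = int(len(new_pheno))
    return SyntheticCohort(
        new_pheno,
        cohort.dosages.loc[persons],
        cohort.snp_weights,
        truth,
        cohort.latent[cohort.latent["person"].isin(persons)].reset_index(drop=True),
    )


def exit_ages(pheno: pd.DataFrame) -> np.ndarray:
    """Age at first of: ovarian cancer, breast cancer, RRSO, death, end of
    follow-up (the censoring rule of the analysis)."""
    cols = ["age_ovca", "age_breast", "age_rrso", "age_death",
            "age_end_followup"]
    return pheno[cols].min(axis=1).values


def reference_incidence(cohort: SyntheticCohort, band_width: float = 5.0,
                        age_min: float = 20.0, age_max: float = 90.0
                        ) -> pd.DataFrame:
    """Expected case fraction by gene x exit-age band, computed from an
    unascertained reference cohort.

    This plays the role of the external age-specific incidence of ovarian
    cancer in carriers: the expected probability that a carrier whose
    follow-up ends in a band is a case, the quantity the kin-cohort weights
    reproduce.
    """
    pheno = cohort.phenotypes
    ages = exit_ages(pheno)
    edges = np.arange(age_min, age_max + band_width, band_width)
    rows = []
    for g in GENES:
        m = pheno["gene"].values == g
        idx = np.clip(np.digitize(ages[m], edges) - 1, 0, len(edges) - 2)
        case = pheno.loc[m, "case"].values
        for b in range(len(edges) - 1):
            sel = idx == b
            if sel.sum() == 0:
                continue
            rows.append({"gene": g, "age_lo": float(edges[b]),
                         "age_hi": float(edges[b + 1]),
                         "prob": float(case[sel].mean()), "n": int(sel.sum())})
    return pd.DataFrame(rows)
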