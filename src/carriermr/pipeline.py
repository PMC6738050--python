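"""Configuration-driven orchestration of the full analysis.

``run_pipeline`` goes from inputs (or a seeded simulation block) to the full
report bundle: the sequential-adjustment table for the scaled genetic score,
subgroup and subtype tables with interaction/heterogeneity p-values, the
per-variant scan, IVW/Egger combination, the TSRI analysis, and a run
manifest. Outputs are plain TSV/JSON and are byte-reproducible for a given
config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cox, io, mr, tsri
from .score import build_raw_scores, fit_scaling, load_snp_weights
from .simulate import (SimConfig, ascertain, reference_incidence,
                       simulate_cohort)
from .survival import (build_weights, fit_weighted_cox, interaction_test,
                       split_episodes, subtype_analysis)

log = logging.getLogger(__name__)

TRAITS = {
    # trait name -> (phenotype column, reporting increment k, unit label)
    "height": ("height_cm", 10.0, "per 10 cm"),
    "bmi_now": ("bmi_now", 5.0, "per 5 kg/m^2"),
    "bmi_young": ("bmi_young", 5.0, "per 5 kg/m^2"),
}
BASE_COVARIATES = [f"pc{i}" for i in range(1, 9)]
LADDER = [
    ("principal components", []),
    ("+ country", ["country"]),
    ("+ birth cohort", ["birth_cohort"]),
    ("+ mutation status", ["gene"]),
    ("+ menopausal status", ["postmenopausal"]),
]


class ConfigError(ValueError):
    pass


class PipelineError(RuntimeError):
    pass


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration (see ``RunConfig.from_yaml``)."""

    trait: str = "height"
    seed: int = 0
    outdir: str = "results"
    inputs: dict | None = None          # phenotypes/dosages/snp_weights/incidence
    simulate: dict | None = None        # SimConfig overrides
    min_info: float = 0.5
    menopause_imputation_age: float = 50.0
    ties: str = "efron"
    weight_band_years: float = 5.0
    alpha: float = 0.05
    bootstrap_b: int = 500
    run_tsri: bool = True
    run_scan: bool = True

    def __post_init__(self):
        if self.trait not in TRAITS:
            raise ConfigError(f"trait must be one of {sorted(TRAITS)}")
        if (self.inputs is None) == (self.simulate is None):
            raise ConfigError(
                "exactly one of 'inputs' and 'simulate' must be given"
            )
        if self.inputs is not None:
            need = {"phenotypes", "dosages", "snp_weights", "incidence"}
            missing = need - set(self.inputs)
            if missing:
                raise ConfigError(f"inputs block missing: {sorted(missing)}")
            for k, v in self.inputs.items():
                if not Path(v).exists():
                    raise ConfigError(f"input file not found: {k}={v}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir")  # output location is not analytic
        blob = json.dumps(d, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


def _load_or_simulate(config: RunConfig):
    """Returns (phenotypes, dosages, snp_weights_raw, incidence)."""
    if config.simulate is not None:
        sim_kw = dict(config.simulate)
        factor = float(sim_kw.pop("case_oversampling_factor", 1.0))
        sim_kw.setdefault("seed", config.seed)
        cohort = simulate_cohort(SimConfig(**sim_kw))
        incidence = reference_incidence(cohort,
                                        band_width=config.weight_band_years)
        if factor > 1:
            cohort = ascertain(cohort, factor, seed=cohort.truth["seed"] + 1)
        return cohort.phenotypes, cohort.dosages, cohort.snp_weights, incidence
    diags = io.validate_inputs(phenotype_path=config.inputs["phenotypes"],
                               dosage_path=config.inputs["dosages"],
                               weights_path=config.inputs["snp_weights"],
                               incidence_path=config.inputs["incidence"])
    if diags:
        raise ConfigError("input validation failed: " + "; ".join(diags))
    return (
        io.read_phenotypes(config.inputs["phenotypes"]),
        io.read_dosages(config.inputs["dosages"]),
        pd.read_csv(config.inputs["snp_weights"], sep="\t",
                    dtype={"chrom": str}),
        io.read_incidence(config.inputs["incidence"]),
    )


def _failure_row(label, n, exc):
    return {"model": label, "n": n, "n_events": np.nan, "hr": np.nan,
            "ci_lo": np.nan, "ci_hi": np.nan, "p": np.nan, "coef": np.nan,
            "robust_se": np.nan, "error": str(exc)}


def _result_row(label, res, term, n):
    t = res.term(term)
    return {
        "model": label, "n": n, "n_events": res.n_events,
        "hr": t["hr"], "ci_lo": t["ci_lo"], "ci_hi": t["ci_hi"],
        "p": t["p"], "coef": t["coef"], "robust_se": t["robust_se"],
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns {artifact name: path} and writes
    the report bundle under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trait_col, k_units, unit_label = TRAITS[config.trait]

    pheno, dosages, weights_raw, incidence = _load_or_simulate(config)
    # quality filter via the standard loader path (round-trip through TSV
    # keeps one loader for both sources)
    tmp_weights = outdir / "_panel.tsv"
    weights_raw.to_csv(tmp_weights, sep="\t", index=False)
    panel = load_snp_weights(tmp_weights, min_quality=config.min_info)
    tmp_weights.unlink()
    n_dropped = panel.attrs.get("n_dropped_quality", 0)

    raw = build_raw_scores(dosages, panel)
    raw_by_row = pheno["person"].map(raw)
    scaling = fit_scaling(raw_by_row, pheno[trait_col], pheno["case"] == 0)
    scaled = scaling.beta0 + scaling.beta1 * raw  # trait units, per person id

    person_weight = build_weights(pheno, incidence)

    eps = split_episodes(pheno, config.menopause_imputation_age)
    eps["gs"] = eps["person"].map(scaled)
    eps["weight"] = eps["person"].map(person_weight)
    scale = {"gs": k_units}
    n_all = pheno["person"].nunique()

    failures: list[str] = []

    # (1) sequential-adjustment ladder
    ladder_rows = []
    covs: list[str] = []
    main = None
    for label, extra in LADDER:
        covs = covs + extra
        try:
            res = fit_weighted_cox(eps, ["gs"] + BASE_COVARIATES + covs,
                                   ties=config.ties, scale=scale)
            ladder_rows.append(_result_row(label, res, "gs", n_all))
            main = res  # final successful ladder row is the headline model
        except cox.CoxError as e:
            failures.append(f"ladder[{label}]: {e}")
            ladder_rows.append(_failure_row(label, n_all, e))
    if main is None:
        raise PipelineError("every ladder model failed: " + "; ".join(failures))
    ladder = pd.DataFrame(ladder_rows)

    # (2) subgroups
    sub_rows = []
    full_covs = BASE_COVARIATES + [c for _, cs in LADDER for c in cs]
    # by mutation status
    for g in ("BRCA1", "BRCA2"):
        sel = eps[eps["gene"] == g]
        covs_g = [c for c in full_covs if c != "gene"]
        try:
            res_g = fit_weighted_cox(sel, ["gs"] + covs_g, ties=config.ties,
                                     scale=scale)
            sub_rows.append(_result_row(f"{g} carriers", res_g, "gs",
                                        sel["person"].nunique()))
        except cox.CoxError as e:
            failures.append(f"subgroup[{g}]: {e}")
            sub_rows.append(_failure_row(f"{g} carriers",
                                         sel["person"].nunique(), e))
    # by menopausal status (time-varying strata)
    for label, flag in (("premenopausal", 0), ("postmenopausal", 1)):
        sel = eps[eps["postmenopausal"] == flag]
        covs_m = [c for c in full_covs if c != "postmenopausal"]
        try:
            res_m = fit_weighted_cox(sel, ["gs"] + covs_m, ties=config.ties,
                                     scale=scale)
            sub_rows.append(_result_row(label, res_m, "gs",
                                        sel["person"].nunique()))
        except cox.CoxError as e:
            failures.append(f"subgroup[{label}]: {e}")
            sub_rows.append(_failure_row(label, sel["person"].nunique(), e))
    interactions = {}
    for name, modifier, drop in (
        ("p_interaction_gene", "gene_num", "gene"),
        ("p_interaction_menopause", "postmenopausal", "postmenopausal"),
    ):
        eps_i = eps.copy()
        if modifier == "gene_num":
            eps_i["gene_num"] = (eps_i["gene"] == "BRCA2").astype(float)
        try:
            _, p_i = interaction_test(
                eps_i, "gs", modifier,
                [c for c in full_covs if c != drop], ties=config.ties)
            interactions[name] = p_i
        except cox.CoxError as e:
            failures.append(f"interaction[{name}]: {e}")
            interactions[name] = None
    subgroups = pd.DataFrame(sub_rows)

    # subtype / grade heterogeneity
    pheno_s = pheno.copy()
    pheno_s["_gs_person"] = pheno_s["person"].map(scaled)
    subtype_out = {}
    for label, partition in (
        ("histology", {"serous": ["serous"],
                       "non-serous": ["mucinous", "endometrioid",
                                      "clear cell", "other"]}),
        ("grade", {"well/moderate": ["well", "moderate"],
                   "poor/undiff": ["poor/undiff"]}),
    ):
        try:
            out = subtype_analysis(
                pheno_s, label, partition, "_gs_person", full_covs,
                incidence=incidence,
                menopause_imputation_age=config.menopause_imputation_age,
                ties=config.ties, scale={"_gs_person": k_units},
            )
        except Exception as e:
            log.warning("subtype analysis %s failed: %s", label, e)
            failures.append(f"subtype[{label}]: {e}")
            continue
        subtype_out[label] = {
            "p_het": out["p_het"],
            "classes": {
                cls: _result_row(cls, r, "_gs_person", r.n)
                for cls, r in out["per_class"].items()
            },
        }

    artifacts = {}

    # (3) per-variant scan and (4) MR combination
    mr_json = None
    if config.run_scan:
        assocs = mr.scan_snps(eps, dosages, panel, full_covs,
                              ties=config.ties)
        # instrument effects in trait units for a per-trait-unit causal slope
        assocs_units = assocs.assign(beta_xg=assocs["beta_xg"] * scaling.beta1)
        est = mr.ivw_estimate(assocs_units)
        hits = mr.count_nominal_hits(assocs, alpha=config.alpha)
        mr_json = {
            "beta_yx_per_trait_unit": est.beta_yx,
            "se_yx": est.se_yx,
            "p": est.p,
            unit_label: est.hr_per_k_units(k_units),
            "q": est.q,
            "i2": est.i2,
            "n_snps": est.n_snps,
            "egger_intercept": est.egger_intercept,
            "egger_intercept_p": est.egger_intercept_p,
            "egger_slope": est.egger_slope,
            "nominal_hits": hits,
        }
        io.write_tsv(assocs, outdir / "per_snp.tsv")
        artifacts["per_snp"] = str(outdir / "per_snp.tsv")
        with open(outdir / "mr_estimate.json", "w") as fh:
            json.dump(mr_json, fh, indent=2, sort_keys=True)
        artifacts["mr_estimate"] = str(outdir / "mr_estimate.json")

    # (5) TSRI
    tsri_json = None
    if config.run_tsri:
        try:
            t = tsri.bootstrap_ci(
                pheno, scaled, trait_col, full_covs[:-1],
                b=config.bootstrap_b, seed=config.seed + 7919,
                weights=person_weight,
                menopause_imputation_age=config.menopause_imputation_age,
                ties=config.ties)
        except (tsri.TsriError, cox.CoxError) as e:
            failures.append(f"tsri: {e}")
            t = None
        if t is not None:
            tsri_json = {
                "beta_per_trait_unit": t.beta,
                "robust_se": t.naive_se,
                "p": t.p,
                unit_label: t.hr_per_k_units(k_units),
                "stage1_f": t.stage1_f,
                "stage1_r2": t.stage1_r2,
                "bootstrap": {"b": t.boot_b, "ci_lo": t.ci_lo,
                              "ci_hi": t.ci_hi, "sd": t.boot_sd,
                              "failures": t.boot_failures, "seed": t.seed},
                "n": t.n,
                "n_events": t.n_events,
            }
            with open(outdir / "tsri.json", "w") as fh:
                json.dump(tsri_json, fh, indent=2, sort_keys=True)
            artifacts["tsri"] = str(outdir / "tsri.json")

    io.write_tsv(ladder, outdir / "sequential_adjustment.tsv")
    io.write_tsv(subgroups, outdir / "subgroups.tsv")
    with open(outdir / "subtypes.json", "w") as fh:
        json.dump({"interactions": interactions, "subtypes": subtype_out},
                  fh, indent=2, sort_keys=True, default=float)
    artifacts.update({
        "sequential_adjustment": str(outdir / "sequential_adjustment.tsv"),
        "subgroups": str(outdir / "subgroups.tsv"),
        "subtypes": str(outdir / "subtypes.json"),
    })

    # (6) manifest
    manifest = {
        "config_sha256": config.digest(),
        "seed": config.seed,
        "trait": config.trait,
        "versions": {
            "carriermr": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_persons": int(n_all),
        "n_events": int(main.n_events),
        "n_snps_used": int(len(panel)),
        "n_snps_dropped_quality": int(n_dropped),
        "n_trait_measured": int(pheno[trait_col].notna().sum()),
        "scaling": {"beta0": scaling.beta0, "beta1": scaling.beta1,
                    "r2": scaling.r2, "n_used": scaling.n_used},
        "artifacts": sorted(artifacts),
        "failures": failures,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    artifacts["manifest"] = str(outdir / "manifest.json")

    return {
        "artifacts": artifacts,
        "ladder": ladder,
        "subgroups": subgroups,
        "interactions": interactions,
        "subtypes": subtype_out,
        "mr": mr_json,
        "tsri": tsri_json,
        "scaling": scaling,
        "manifest": manifest,
    }
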