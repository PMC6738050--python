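"""Reading, writing and validation of the pipeline's TSV inputs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .score import WEIGHT_COLUMNS

PHENOTYPE_REQUIRED = [
    "person", "family", "gene", "birth_year", "country",
    "pc1", "pc2", "pc3", "pc4", "pc5", "pc6", "pc7", "pc8",
    "case", "age_ovca", "age_breast", "age_rrso", "age_death",
    "age_end_followup", "age_menopause_natural",
    "height_cm", "bmi_now", "bmi_young", "parity", "age_menarche",
]


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_dosages(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="person")
    return df


def read_incidence(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.8g")


def validate_inputs(phenotype_path, dosage_path, weights_path,
                    incidence_path=None) -> list[str]:
    """Schema, range and cross-file consistency checks.

    Returns a list of human-readable diagnostics; empty means the inputs are
    usable. Diagnostics are returned, never raised.
    """
    diags: list[str] = []
    try:
        pheno = read_phenotypes(phenotype_path)
    except Exception as e:  # pragma: no cover - filesystem failures
        return [f"phenotypes: unreadable ({e})"]
    try:
        dos = read_dosages(dosage_path)
    except Exception as e:
        return [f"dosages: unreadable ({e})"]
    try:
        weights = pd.read_csv(weights_path, sep="\t")
    except Exception as e:
        return [f"snp_weights: unreadable ({e})"]

    for col in PHENOTYPE_REQUIRED:
        if col not in pheno.columns:
            diags.append(f"phenotypes: missing column {col!r}")
    for col in WEIGHT_COLUMNS:
        if col not in weights.columns:
            diags.append(f"snp_weights: missing column {col!r}")
    if diags:
        return diags

    if pheno["person"].duplicated().any():
        diags.append("phenotypes: duplicate person ids")
    bad_gene = ~pheno["gene"].isin(["BRCA1", "BRCA2"])
    if bad_gene.any():
        diags.append(f"phenotypes: {int(bad_gene.sum())} rows with gene not "
                     "in {BRCA1, BRCA2}")
    ages = pheno[["age_ovca", "age_breast", "age_rrso", "age_death",
                  "age_end_followup"]]
    if ages.notna().sum(axis=1).eq(0).any():
        n = int(ages.notna().sum(axis=1).eq(0).sum())
        diags.append(f"phenotypes: {n} persons with no event/censoring age")
    out_of_range = (ages.stack() <= 0) | (ages.stack() >= 110)
    if out_of_range.any():
        diags.append(f"phenotypes: {int(out_of_range.sum())} ages outside "
                     "(0, 110)")
    case_no_age = (pheno["case"] == 1) & pheno["age_ovca"].isna()
    if case_no_age.any():
        diags.append(f"phenotypes: {int(case_no_age.sum())} cases without "
                     "age_ovca")

    vals = dos.to_numpy(float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 2:
        bad = int(((vals < 0) | (vals > 2)).sum())
        diags.append(f"dosages: {bad} values outside [0, 2]")
    missing_person = ~pheno["person"].isin(dos.index)
    if missing_person.any():
        diags.append(f"dosages: {int(missing_person.sum())} phenotype "
                     "persons absent from dosage matrix")
    missing_rsid = [r for r in weights["rsid"] if r not in dos.columns]
    if missing_rsid:
        diags.append(f"dosages: {len(missing_rsid)} weight rsids absent "
                     f"from dosage header (e.g. {missing_rsid[:3]})")

    if incidence_path is not None:
        try:
            inc = read_incidence(incidence_path)
        except Exception as e:
            return diags + [f"incidence: unreadable ({e})"]
        for col in ("gene", "age_lo", "age_hi", "prob"):
            if col not in inc.columns:
                diags.append(f"incidence: missing column {col!r}")
        if "prob" in inc.columns and ((inc["prob"] < 0) | (inc["prob"] > 1)).any():
            diags.append("incidence: prob outside [0, 1]")
    return diags
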