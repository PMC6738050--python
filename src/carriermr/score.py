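"""Genetic-score construction and trait-unit scaling.

A genetic score (GS) is the weighted sum of effect-allele dosages,
``GS = sum_i beta_XGi * SNP_i``, with per-allele weights taken from external
GWAS. Because the weights are on the GWAS scale, the raw score is rescaled to
trait units (cm, kg/m^2) by ordinary least squares of the measured trait on
the raw score among non-case carriers: ``scaled = beta0 + beta1 * raw``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger(__name__)

WEIGHT_COLUMNS = ["rsid", "chrom", "pos", "effect_allele", "other_allele",
                  "beta", "eaf", "info"]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ScoreError(ValueError):
    """Raised for malformed weight panels or unresolvable alleles."""


@dataclass
class ScalingModel:
    """OLS fit of trait on raw score among non-case carriers."""

    beta0: float          # intercept, trait units
    beta1: float          # slope, trait units per raw-score unit
    r2: float             # variation in trait explained by the score
    n_used: int

    def apply(self, raw_scores: pd.Series) -> pd.Series:
        return self.beta0 + self.beta1 * raw_scores


def load_snp_weights(weights_file, min_quality: float = 0.5) -> pd.DataFrame:
    """Load a SNP-weight TSV, dropping variants with imputation quality
    below ``min_quality`` (the conventional info < 0.5 exclusion; a variant
    at exactly the threshold is retained)."""
    df = pd.read_csv(weights_file, sep="\t", dtype={"chrom": str})
    missing = [c for c in WEIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise ScoreError(f"weight file missing column(s): {missing}")
    if df["rsid"].duplicated().any():
        dups = df.loc[df["rsid"].duplicated(), "rsid"].tolist()
        raise ScoreError(f"duplicate rsID(s) in weight file: {dups[:5]}")
    bad_alleles = ~(
        df["effect_allele"].isin(_COMPLEMENT) & df["other_allele"].isin(_COMPLEMENT)
    )
    if bad_alleles.any():
        raise ScoreError(
            f"non-ACGT alleles for {df.loc[bad_alleles, 'rsid'].tolist()[:5]}"
        )
    if not df["beta"].apply(np.isfinite).all():
        raise ScoreError("non-finite beta in weight file")
    if ((df["eaf"] <= 0) | (df["eaf"] >= 1)).any():
        raise ScoreError("eaf outside (0, 1) in weight file")
    kept = df[df["info"] >= min_quality].reset_index(drop=True)
    n_dropped = len(df) - len(kept)
    log.info("load_snp_weights: %d variants read, %d dropped by quality < %s",
             len(df), n_dropped, min_quality)
    kept.attrs["n_dropped_quality"] = n_dropped
    return kept


def align_alleles(weights: pd.DataFrame, genotype_alleles: pd.DataFrame
                  ) -> pd.DataFrame:
    """Resolve effect-allele orientation of a dosage source against a weight
    panel.

    ``genotype_alleles`` has columns rsid, counted_allele, other_allele
    describing which allele each dosage column counts. Returns a copy of
    ``weights`` with a ``flip`` column: dosages for flipped variants must be
    replaced by ``2 - dosage``. Matching allows strand complements;
    strand-ambiguous A/T and C/G variants are rejected when their EAF is in
    [0.4, 0.6] (orientation undecidable there).
    """
    ga = genotype_alleles.set_index("rsid")
    out = weights.copy()
    flips = []
    failures = []
    for _, row in out.iterrows():
        rsid, e, o = row["rsid"], row["effect_allele"], row["other_allele"]
        if rsid not in ga.index:
            failures.append(rsid)
            continue
        c, co = ga.loc[rsid, "counted_allele"], ga.loc[rsid, "other_allele"]
        ambiguous = _COMPLEMENT[e] == o
        if ambiguous and 0.4 <= row["eaf"] <= 0.6:
            failures.append(rsid)
            continue
        if (c, co) == (e, o) or (not ambiguous and
                                 (c, co) == (_COMPLEMENT[e], _COMPLEMENT[o])):
            flips.append(False)
        elif (c, co) == (o, e) or (not ambiguous and
                                   (c, co) == (_COMPLEMENT[o], _COMPLEMENT[e])):
            flips.append(True)
        else:
            failures.append(rsid)
    if failures:
        raise ScoreError(f"unresolvable allele orientation for: {failures}")
    out["flip"] = flips
    return out


def build_raw_scores(genotypes: pd.DataFrame, weights: pd.DataFrame
                     ) -> pd.Series:
    """Weighted sum of effect-allele dosages per person.

    ``genotypes`` is persons x rsids with dosages in [0, 2] counting the
    effect allele (apply :func:`align_alleles` first if orientation is
    unresolved). Missing person-variant dosages are mean-imputed as
    ``2 * eaf`` from the weight panel.
    """
    missing = [r for r in weights["rsid"] if r not in genotypes.columns]
    if missing:
        raise ScoreError(f"weight rsid(s) absent from genotypes: {missing[:5]}")
    G = genotypes[weights["rsid"].values].to_numpy(dtype=float, copy=True)
    if np.nanmin(G) < 0 or np.nanmax(G) > 2:
        raise ScoreError("dosages outside [0, 2]")
    if "flip" in weights.columns:
        f = weights["flip"].to_numpy(bool)
        G[:, f] = 2.0 - G[:, f]
    nan_mask = np.isnan(G)
    if nan_mask.any():
        fill = np.broadcast_to(2.0 * weights["eaf"].to_numpy(), G.shape)
        G[nan_mask] = fill[nan_mask]
    raw = G @ weights["beta"].to_numpy()
    return pd.Series(raw, index=genotypes.index, name="raw_score")


def fit_scaling(raw_scores: pd.Series, trait: pd.Series,
                non_case: pd.Series) -> ScalingModel:
    """OLS of the measured trait on the raw score among non-case carriers
    with both quantities observed."""
    mask = non_case.astype(bool) & raw_scores.notna() & trait.notna()
    if mask.sum() < 3:
        raise ScoreError(
            f"need >= 3 non-case persons with score and trait, got {int(mask.sum())}"
        )
    x = raw_scores[mask].to_numpy()
    y = trait[mask].to_numpy()
    if np.ptp(x) == 0:
        raise ScoreError("zero variance in raw scores (degenerate regression)")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return ScalingModel(
        beta0=float(fit.params[0]),
        beta1=float(fit.params[1]),
        r2=float(fit.rsquared),
        n_used=int(mask.sum()),
    )


def build_scores(genotypes: pd.DataFrame, weights: pd.DataFrame,
                 trait: pd.Series, non_case: pd.Series
                 ) -> tuple[pd.DataFrame, ScalingModel]:
    """Raw and trait-scaled scores plus the fitted scaling model."""
    raw = build_raw_scores(genotypes, weights)
    model = fit_scaling(raw, trait, non_case)
    out = pd.DataFrame({"raw_score": raw, "scaled_score": model.apply(raw)})
    return out, model


def cross_trait_check(scaled_scores: pd.Series, other_trait: pd.Series) -> dict:
    """Simple linear regression of another trait on the scaled score, for
    pleiotropy inspection (no decision logic)."""
    mask = scaled_scores.notna() & other_trait.notna()
    x = scaled_scores[mask].to_numpy()
    y = other_trait[mask].to_numpy()
    if mask.sum() < 3 or np.ptp(x) == 0:
        raise ScoreError("degenerate cross-trait regression")
    if np.ptp(y) == 0:
        raise ScoreError("constant trait in cross-trait regression")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "slope": float(fit.params[1]),
        "se": float(fit.bse[1]),
        "p": float(fit.pvalues[1]),
        "n": int(mask.sum()),
    }
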