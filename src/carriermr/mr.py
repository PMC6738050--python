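"""Per-variant outcome scan and Mendelian-randomisation estimators.

Each instrument i carries an external per-allele trait effect ``beta_XGi``
and, from the carrier cohort, a per-allele log hazard ratio ``beta_YGi`` with
standard error ``se_YGi`` estimated by a multivariate-adjusted weighted Cox
model. The combined causal effect of the trait on the log hazard is the
inverse-variance-weighted (IVW) estimator

    beta_YX = sum_i beta_XGi * beta_YGi * se_i^-2 / sum_i beta_XGi^2 * se_i^-2
    SE_YX   = sqrt(1 / sum_i beta_XGi^2 * se_i^-2)

equivalently the slope of an SE^-2-weighted through-origin regression of
beta_YG on beta_XG. Cochran's Q / I^2 on the per-variant Wald ratios measure
heterogeneity, and MR-Egger (weighted regression with a free intercept, all
beta_XG oriented positive) probes directional pleiotropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import cox
from .survival import fit_weighted_cox, wald_p

log = logging.getLogger(__name__)


class MrError(ValueError):
    pass


@dataclass
class IvwEstimate:
    beta_yx: float            # log HR per trait unit
    se_yx: float
    p: float
    q: float | None           # Cochran Q of Wald ratios
    i2: float | None          # max(0, (Q - df) / Q)
    n_snps: int
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    egger_slope: float | None = None

    def hr_per_k_units(self, k: float) -> dict:
        """HR and 95% CI per ``k`` trait units (e.g. 10 cm, 5 kg/m^2)."""
        return {
            "hr": float(np.exp(k * self.beta_yx)),
            "ci_lo": float(np.exp(k * self.beta_yx - 1.96 * k * self.se_yx)),
            "ci_hi": float(np.exp(k * self.beta_yx + 1.96 * k * self.se_yx)),
        }


def scan_snps(episodes: pd.DataFrame, genotypes: pd.DataFrame,
              snp_weights: pd.DataFrame, covariates: list[str],
              weights="weight", **kw) -> pd.DataFrame:
    """One weighted Cox fit per variant: outcome on dosage plus covariates.

    Returns a per-variant table (rsid, beta_xg, beta_yg, se_yg, p, eaf,
    info, ...). Variants whose fit fails (constant dosage, separation,
    non-convergence) are flagged ``excluded`` and carry NaN estimates; they
    are dropped from downstream combination.
    """
    rows = []
    eps = episodes.copy()
    for _, snp in snp_weights.iterrows():
        rsid = snp["rsid"]
        eps["_dosage"] = eps["person"].map(genotypes[rsid]).to_numpy(float)
        try:
            res = fit_weighted_cox(eps, ["_dosage"] + covariates,
                                   weights=weights, **kw)
            t = res.terms.loc["_dosage"]
            rows.append({"rsid": rsid, "beta_xg": float(snp["beta"]),
                         "beta_yg": float(t["coef"]),
                         "se_yg": float(t["robust_se"]), "p": float(t["p"]),
                         "eaf": float(snp["eaf"]), "info": float(snp["info"]),
                         "excluded": False})
        except cox.CoxError as e:
            log.warning("scan_snps: %s excluded (%s)", rsid, e)
            rows.append({"rsid": rsid, "beta_xg": float(snp["beta"]),
                         "beta_yg": np.nan, "se_yg": np.nan, "p": np.nan,
                         "eaf": float(snp["eaf"]), "info": float(snp["info"]),
                         "excluded": True})
    out = pd.DataFrame(rows)
    n_exc = int(out["excluded"].sum())
    if n_exc:
        log.info("scan_snps: %d/%d variants excluded", n_exc, len(out))
    return out


def _usable(assocs: pd.DataFrame) -> pd.DataFrame:
    a = assocs
    if "excluded" in a.columns:
        a = a[~a["excluded"]]
    a = a.dropna(subset=["beta_xg", "beta_yg", "se_yg"])
    if (a["se_yg"] <= 0).any():
        raise MrError("non-positive se_yg")
    return a


def ivw_estimate(assocs: pd.DataFrame, egger: bool = True) -> IvwEstimate:
    """IVW combination of per-variant associations (fixed effect), with
    heterogeneity and optionally MR-Egger attached."""
    a = _usable(assocs)
    if len(a) < 1:
        raise MrError("no usable associations")
    bx = a["beta_xg"].to_numpy()
    by = a["beta_yg"].to_numpy()
    se = a["se_yg"].to_numpy()
    denom = np.sum(bx**2 / se**2)
    if denom == 0:
        raise MrError("all beta_xg are zero: IVW estimator undefined")
    beta_yx = float(np.sum(bx * by / se**2) / denom)
    se_yx = float(np.sqrt(1.0 / denom))
    q = i2 = None
    if len(a) >= 2:
        q, i2 = heterogeneity(a)
    est = IvwEstimate(
        beta_yx=beta_yx, se_yx=se_yx, p=wald_p(beta_yx, se_yx),
        q=q, i2=i2, n_snps=int(len(a)),
    )
    if egger and len(a) >= 3:
        eg = egger_test(a)
        est.egger_intercept = eg["intercept"]
        est.egger_intercept_se = eg["intercept_se"]
        est.egger_intercept_p = eg["intercept_p"]
        est.egger_slope = eg["slope"]
    return est


def heterogeneity(assocs: pd.DataFrame) -> tuple[float, float]:
    """Cochran Q and I^2 of the per-variant Wald ratios about the IVW mean.

    Ratio estimates ``beta_yg / beta_xg`` with first-order SEs
    ``se_yg / |beta_xg|``; with these weights the IVW mean of the ratios is
    exactly the IVW slope, so Q reduces to the fixed-effect meta-analysis Q.
    """
    a = _usable(assocs)
    if len(a) < 2:
        raise MrError("heterogeneity needs >= 2 associations")
    bx = a["beta_xg"].to_numpy()
    if np.any(bx == 0):
        raise MrError("beta_xg of zero: ratio estimate undefined")
    ratio = a["beta_yg"].to_numpy() / bx
    rse = a["se_yg"].to_numpy() / np.abs(bx)
    w = rse**-2
    mean = np.sum(w * ratio) / np.sum(w)
    q = float(np.sum(w * (ratio - mean) ** 2))
    df = len(a) - 1
    i2 = float(max(0.0, (q - df) / q)) if q > 0 else 0.0
    return q, i2


def egger_test(assocs: pd.DataFrame) -> dict:
    """MR-Egger: SE^-2-weighted regression of beta_YG on beta_XG with a free
    intercept, after orienting all beta_XG >= 0 (flipping beta_YG along).

    SEs follow the multiplicative random-effects convention: scaled by
    ``max(1, sqrt(residual variance))`` so under-dispersion never tightens
    them.
    """
    a = _usable(assocs)
    if len(a) < 3:
        raise MrError(f"Egger regression needs >= 3 associations, got {len(a)}")
    sign = np.where(a["beta_xg"].to_numpy() < 0, -1.0, 1.0)
    bx = a["beta_xg"].to_numpy() * sign
    by = a["beta_yg"].to_numpy() * sign
    se = a["se_yg"].to_numpy()
    if np.ptp(bx) == 0:
        raise MrError("no variation in beta_xg: Egger slope unidentified")
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=se**-2).fit()
    sigma = np.sqrt(fit.scale)
    infl = max(1.0, sigma) / sigma if sigma > 0 else 1.0
    bse = fit.bse * infl
    tval = fit.params[0] / bse[0]
    # t reference on k-2 df, as in the original formulation
    p_int = float(2 * stats.t.sf(abs(tval), df=len(a) - 2))
    return {
        "intercept": float(fit.params[0]),
        "intercept_se": float(bse[0]),
        "intercept_p": p_int,
        "slope": float(fit.params[1]),
        "slope_se": float(bse[1]),
        "n_snps": int(len(a)),
    }


def rescale_per_sd(beta_per_sd: float, trait_sd_in_controls: float,
                   k_units: float) -> float:
    """HR per ``k`` trait units from an effect per trait z-score among
    controls: ``exp(beta * k / sd)``."""
    if trait_sd_in_controls <= 0:
        raise MrError("trait SD must be positive")
    return float(np.exp(beta_per_sd * k_units / trait_sd_in_controls))


def count_nominal_hits(assocs: pd.DataFrame, alpha: float = 0.05,
                       bonferroni: bool = True) -> dict:
    """Count variants nominally associated with the outcome, and after
    Bonferroni correction over the panel."""
    a = _usable(assocs)
    p = a["p"].to_numpy()
    k = len(a)
    nominal = a[p < alpha]
    out = {
        "n_tested": k,
        "n_nominal": int(len(nominal)),
        "nominal_rsids": nominal["rsid"].tolist(),
    }
    if bonferroni:
        adj = a[p < alpha / max(k, 1)]
        out["n_bonferroni"] = int(len(adj))
        out["bonferroni_rsids"] = adj["rsid"].tolist()
    return out
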