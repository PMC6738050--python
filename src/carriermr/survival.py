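"""Kin-cohort weights, counting-process episodes, and weighted Cox models.

Clinic-based carrier cohorts oversample affected families, so an unweighted
Cox model is biased. The kin-cohort correction assigns, within each
gene x exit-age stratum with observed case fraction ``p_obs`` and externally
expected fraction ``p_exp``, weight ``p_exp / p_obs`` to cases and
``(1 - p_exp) / (1 - p_obs)`` to non-cases; the weighted case fraction then
matches the external incidence exactly.

Persons are expanded into (start, stop] episodes on the age timescale with a
time-varying postmenopausal indicator, and models are fitted by the weighted
partial-likelihood engine in :mod:`carriermr.cox` with a family-clustered
sandwich variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import cox
from .simulate import exit_ages

log = logging.getLogger(__name__)

EXIT_COLUMNS = ["age_ovca", "age_breast", "age_rrso", "age_death",
                "age_end_followup"]
PCS = [f"pc{i}" for i in range(1, 9)]


class SurvivalError(ValueError):
    pass


@dataclass
class CoxResult:
    """Weighted Cox fit on a named covariate set, reported as HRs.

    ``scale`` multiplies the coefficient before exponentiation, so an HR can
    be reported per 10 cm of height or per 5 kg/m^2 of BMI.
    """

    terms: pd.DataFrame     # coef, naive_se, robust_se, hr, ci_lo, ci_hi, p
    loglik: float
    n: int
    n_events: int
    n_clusters: int
    ties: str
    converged: bool
    n_iter: int
    scale: dict = field(default_factory=dict)  # term -> reporting multiplier

    def term(self, name: str) -> pd.Series:
        return self.terms.loc[name]


def wald_p(coef: float, robust_se: float) -> float:
    """Two-sided Wald p-value, ``2 * (1 - Phi(|coef| / se))``."""
    if robust_se <= 0:
        raise SurvivalError(f"robust SE must be positive, got {robust_se}")
    p = float(2.0 * stats.norm.sf(abs(coef) / robust_se))
    return max(p, np.finfo(float).tiny)  # keep p in (0, 1] under underflow


# ---------------------------------------------------------------------------
# kin-cohort weights
# ---------------------------------------------------------------------------

def build_weights(pheno: pd.DataFrame, incidence: pd.DataFrame,
                  min_stratum: int = 10) -> pd.Series:
    """Per-person kin-cohort weights from external incidence.

    ``incidence`` has columns gene, age_lo, age_hi, prob where ``prob`` is
    the expected case fraction among carriers of that gene whose follow-up
    ends in the age band. Strata with fewer than ``min_stratum`` persons or
    an observed case fraction of exactly 0 or 1 are merged with the next
    lower band (the merge is logged).
    """
    ages = exit_ages(pheno)
    case = pheno["case"].to_numpy(dtype=bool)
    weights = np.ones(len(pheno))
    for gene, inc_g in incidence.groupby("gene", sort=True):
        gmask = (pheno["gene"] == gene).to_numpy()
        if not gmask.any():
            continue
        inc_g = inc_g.sort_values("age_lo").reset_index(drop=True)
        edges = np.append(inc_g["age_lo"].to_numpy(), inc_g["age_hi"].iloc[-1])
        band = np.clip(np.digitize(ages[gmask], edges) - 1, 0, len(inc_g) - 1)
        # accumulate strata, merging sparse/degenerate ones downward
        groups: list[list[int]] = []
        pending: list[int] = []
        for b in range(len(inc_g)):
            pending.append(b)
            rows = np.isin(band, pending)
            n_b = int(rows.sum())
            if n_b == 0:
                continue
            p_obs = float(case[gmask][rows].mean())
            if n_b >= min_stratum and 0.0 < p_obs < 1.0:
                groups.append(pending)
                pending = []
        if pending:
            if groups:
                groups[-1].extend(pending)
            else:
                groups.append(pending)
            log.info("build_weights: merged trailing band(s) %s for %s",
                     pending, gene)
        for grp in groups:
            rows = np.isin(band, grp)
            if not rows.any():
                continue
            n_g = inc_g["n"] if "n" in inc_g.columns else None
            if n_g is not None:
                tot = float(n_g.iloc[grp].sum())
                p_exp = float((inc_g["prob"].iloc[grp] * n_g.iloc[grp]).sum() / tot) \
                    if tot > 0 else float(inc_g["prob"].iloc[grp].mean())
            else:
                p_exp = float(inc_g["prob"].iloc[grp].mean())
            p_exp = min(max(p_exp, 1e-6), 1 - 1e-6)
            p_obs = float(case[gmask][rows].mean())
            if not 0.0 < p_obs < 1.0:
                log.warning("build_weights: degenerate merged stratum %s/%s "
                            "(p_obs=%s); weights left at 1", gene, grp, p_obs)
                continue
            idx = np.flatnonzero(gmask)[rows]
            weights[idx] = np.where(case[idx], p_exp / p_obs,
                                    (1 - p_exp) / (1 - p_obs))
    return pd.Series(weights, index=pd.Index(pheno["person"].to_numpy(),
                                             name="person"), name="weight")


# ---------------------------------------------------------------------------
# episode construction
# ---------------------------------------------------------------------------

def menopause_age(pheno: pd.DataFrame, imputation_age: float = 50.0
                  ) -> np.ndarray:
    """Age at menopause: natural menopause, or RRSO if earlier (surgical),
    imputed at ``imputation_age`` when unknown."""
    nat = pheno["age_menopause_natural"].to_numpy(dtype=float)
    rrso = pheno["age_rrso"].to_numpy(dtype=float) if "age_rrso" in pheno \
        else np.full(len(pheno), np.nan)
    m = np.where(np.isnan(nat), imputation_age, nat)
    return np.fmin(m, np.where(np.isnan(rrso), np.inf, rrso))


def split_episodes(pheno: pd.DataFrame, menopause_imputation_age: float = 50.0
                   ) -> pd.DataFrame:
    """Counting-process expansion with a time-varying postmenopausal flag.

    Exit age is the first of ovarian-cancer diagnosis, breast-cancer
    diagnosis, RRSO, death, or end of follow-up; only ovarian cancer is an
    event. Each person contributes a premenopausal row from birth and, if
    menopause precedes exit, a postmenopausal row; event flags sit on the
    final row. Person-level columns are carried onto every row.
    """
    exit_age = exit_ages(pheno)
    if np.isnan(exit_age).any():
        bad = pheno.loc[np.isnan(exit_age), "person"].tolist()[:5]
        raise SurvivalError(f"no exit age for person(s): {bad}")
    if (exit_age <= 0).any():
        raise SurvivalError("non-positive exit age")
    event = (
        pheno["age_ovca"].notna()
        & np.isclose(pheno["age_ovca"].to_numpy(dtype=float), exit_age)
    ).to_numpy()
    meno = menopause_age(pheno, menopause_imputation_age)
    split = (meno > 0) & (meno < exit_age)

    carry = pheno.drop(columns=[c for c in EXIT_COLUMNS if c in pheno], errors="ignore")
    pre = carry.copy()
    pre["start"] = 0.0
    pre["stop"] = np.where(split, meno, exit_age)
    pre["event"] = np.where(split, 0, event.astype(int))
    pre["postmenopausal"] = 0
    post = carry.loc[split].copy()
    post["start"] = meno[split]
    post["stop"] = exit_age[split]
    post["event"] = event[split].astype(int)
    post["postmenopausal"] = 1
    episodes = pd.concat([pre, post], ignore_index=True)
    episodes = episodes.sort_values(["person", "start"]).reset_index(drop=True)
    if (episodes["start"] >= episodes["stop"]).any():
        raise SurvivalError("negative or empty episode span")
    return episodes


# ---------------------------------------------------------------------------
# covariate coding and fitting
# ---------------------------------------------------------------------------

def birth_decade(birth_year: pd.Series) -> pd.Series:
    return ((birth_year // 10) * 10).astype(int).astype(str)


def design_matrix(episodes: pd.DataFrame, covariates: list[str]
                  ) -> tuple[np.ndarray, list[str]]:
    """Expand a covariate spec into a numeric design matrix.

    Numeric columns enter as-is; ``birth_cohort`` codes birth year as decade
    categories; other non-numeric columns become dummy blocks (first level
    dropped).
    """
    blocks, names = [], []
    for cov in covariates:
        if cov == "birth_cohort":
            col = birth_decade(episodes["birth_year"])
        elif cov in episodes.columns:
            col = episodes[cov]
        else:
            raise SurvivalError(f"unknown covariate {cov!r}")
        if pd.api.types.is_numeric_dtype(col):
            blocks.append(col.to_numpy(dtype=float)[:, None])
            names.append(cov)
        else:
            col = col.astype(str)
            if "event" in episodes.columns:
                # a level with no events drives its dummy to -inf (monotone
                # likelihood); merge such levels into the modal level
                ev_by_level = episodes["event"].groupby(col).sum()
                dead = ev_by_level.index[ev_by_level == 0]
                if len(dead) and len(dead) < col.nunique():
                    mode = col.mode().iloc[0]
                    log.info("design_matrix: merging zero-event %s level(s) "
                             "%s into %r", cov, list(dead), mode)
                    col = col.where(~col.isin(dead), mode)
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True)
            dummies = dummies[sorted(dummies.columns)]
            blocks.append(dummies.to_numpy(dtype=float))
            names.extend(dummies.columns)
    X = np.hstack(blocks)
    if np.isnan(X).any():
        bad = [names[j] for j in np.unique(np.nonzero(np.isnan(X))[1])]
        raise SurvivalError(f"missing values in covariate(s): {bad}")
    return X, names


def fit_weighted_cox(episodes: pd.DataFrame, covariates: list[str],
                     weights: str | pd.Series | None = "weight",
                     cluster: str = "family", ties: str = "efron",
                     scale: dict | None = None) -> CoxResult:
    """Weighted Cox fit with family-clustered robust variance.

    ``covariates`` name columns of ``episodes`` (plus the synthetic
    ``birth_cohort`` decade coding); ``weights`` is a column name, a Series
    aligned to persons, or None for unweighted.
    """
    X, names = design_matrix(episodes, covariates)
    if isinstance(weights, str):
        w = episodes[weights].to_numpy(dtype=float) if weights in episodes else None
        if w is None and weights != "weight":
            raise SurvivalError(f"weight column {weights!r} not found")
    elif isinstance(weights, pd.Series):
        w = episodes["person"].map(weights).to_numpy(dtype=float)
        if np.isnan(w).any():
            missing = episodes.loc[np.isnan(w), "person"].unique()[:5]
            raise SurvivalError(f"no weight for person(s): {list(missing)}")
    else:
        w = None
    clusters = episodes[cluster].to_numpy() if cluster else None
    fit = cox.fit_cox(
        X,
        episodes["start"].to_numpy(dtype=float),
        episodes["stop"].to_numpy(dtype=float),
        episodes["event"].to_numpy(),
        weights=w,
        clusters=clusters,
        ties=ties,
        names=names,
    )
    scale = scale or {}
    k = np.array([scale.get(nm, 1.0) for nm in names])
    terms = pd.DataFrame(
        {
            "coef": fit.coef,
            "naive_se": fit.naive_se,
            "robust_se": fit.robust_se,
            "hr": np.exp(k * fit.coef),
            "ci_lo": np.exp(k * fit.coef - 1.96 * np.abs(k) * fit.robust_se),
            "ci_hi": np.exp(k * fit.coef + 1.96 * np.abs(k) * fit.robust_se),
            "p": [wald_p(c, s) for c, s in zip(fit.coef, fit.robust_se)],
        },
        index=pd.Index(names, name="term"),
    )
    n_persons = episodes["person"].nunique() if "person" in episodes else fit.n_obs
    return CoxResult(
        terms=terms,
        loglik=fit.loglik,
        n=int(n_persons),
        n_events=fit.n_events,
        n_clusters=fit.n_clusters,
        ties=fit.ties,
        converged=fit.converged,
        n_iter=fit.n_iter,
        scale=scale,
    )


def interaction_test(episodes: pd.DataFrame, exposure: str, modifier: str,
                     covariates: list[str] | None = None, **kw
                     ) -> tuple[CoxResult, float]:
    """Wald test of an exposure x modifier product term.

    With a time-varying modifier (postmenopausal status) this is a test of
    proportional hazards for the exposure across the modifier's levels.
    """
    eps = episodes.copy()
    mod = eps[modifier]
    if mod.nunique() < 2:
        raise SurvivalError(f"modifier {modifier!r} does not vary")
    prod = f"{exposure}:{modifier}"
    eps[prod] = eps[exposure].to_numpy(dtype=float) * mod.to_numpy(dtype=float)
    covs = [exposure, modifier] + (covariates or []) + [prod]
    res = fit_weighted_cox(eps, covs, **kw)
    return res, float(res.terms.loc[prod, "p"])


def censor_other_class(pheno: pd.DataFrame, label: str, cls: str
                       ) -> pd.DataFrame:
    """Cases of the complementary class become censored at diagnosis age."""
    out = pheno.copy()
    other = (out["case"] == 1) & (out[label] != cls)
    out.loc[other, "age_end_followup"] = out.loc[other, "age_ovca"]
    out.loc[other, "age_ovca"] = np.nan
    out.loc[other, "case"] = 0
    return out


def subtype_analysis(pheno: pd.DataFrame, label: str, partition: dict,
                     exposure: str, covariates: list[str],
                     incidence: pd.DataFrame | None = None,
                     weights: pd.Series | None = None,
                     menopause_imputation_age: float = 50.0,
                     **kw) -> dict:
    """Per-class weighted Cox fits with a two-sample heterogeneity test.

    ``partition`` maps class name -> list of raw labels (e.g. serous vs the
    non-serous histologies). Cases outside the class are censored at
    diagnosis. p_het is a Wald test on the difference of the class
    coefficients using robust SEs (independence approximation).
    """
    mapping = {raw: cls for cls, raws in partition.items() for raw in raws}
    work = pheno.copy()
    work["_class"] = work[label].map(mapping)
    results = {}
    for cls in partition:
        sub = work.copy()
        sub[label] = sub["_class"]
        sub = censor_other_class(sub, label, cls)
        if sub["case"].sum() == 0:
            log.warning("subtype_analysis: class %r has zero events", cls)
            continue
        eps = split_episodes(sub.drop(columns="_class"),
                             menopause_imputation_age)
        # censoring reassignment changes the case mix, so kin-cohort weights
        # are rebuilt per class when an incidence table is supplied
        w = build_weights(sub, incidence) if incidence is not None else weights
        results[cls] = fit_weighted_cox(eps, [exposure] + covariates,
                                        weights=w, **kw)
    p_het = None
    if len(results) == 2:
        (r1, r2) = results.values()
        b1, s1 = r1.terms.loc[exposure, ["coef", "robust_se"]]
        b2, s2 = r2.terms.loc[exposure, ["coef", "robust_se"]]
        p_het = wald_p(float(b1 - b2), float(np.hypot(s1, s2)))
    return {"per_class": results, "p_het": p_het}
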