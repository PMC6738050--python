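"""Two-stage residual inclusion (TSRI) instrumental-variable analysis.

Stage one regresses the measured trait on the genetic score and covariates
by OLS; stage two fits a weighted Cox model for the outcome on the measured
trait, the covariates, and the stage-one residual. Including the residual
(a control function) absorbs the confounded part of the trait, so the
stage-two trait coefficient estimates the causal log hazard ratio per trait
unit. Uncertainty comes from a cluster bootstrap that resamples whole
families with replacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import cox
from .survival import (SurvivalError, design_matrix, fit_weighted_cox,
                       split_episodes, wald_p)

log = logging.getLogger(__name__)


class TsriError(ValueError):
    pass


@dataclass
class TsriResult:
    beta: float               # stage-2 log HR per trait unit
    naive_se: float           # robust SE from the stage-2 Cox fit
    p: float
    stage1_coef_gs: float
    stage1_f: float           # partial F of the score in stage 1
    stage1_r2: float
    n: int
    n_events: int
    boot_b: int | None = None
    ci_lo: float | None = None
    ci_hi: float | None = None
    boot_sd: float | None = None
    boot_failures: int = 0
    seed: int | None = None

    def hr_per_k_units(self, k: float) -> dict:
        lo = self.ci_lo if self.ci_lo is not None else self.beta - 1.96 * self.naive_se
        hi = self.ci_hi if self.ci_hi is not None else self.beta + 1.96 * self.naive_se
        return {
            "hr": float(np.exp(k * self.beta)),
            "ci_lo": float(np.exp(k * lo)),
            "ci_hi": float(np.exp(k * hi)),
        }


def _prepare(pheno: pd.DataFrame, scores: pd.Series, trait_col: str,
             min_n: int) -> pd.DataFrame:
    df = pheno.copy()
    df["_gs"] = df["person"].map(scores)
    df = df[df[trait_col].notna() & df["_gs"].notna()].reset_index(drop=True)
    if len(df) < min_n:
        raise TsriError(f"only {len(df)} persons with trait and score "
                        f"(minimum {min_n})")
    return df


def tsri_fit(pheno: pd.DataFrame, scores: pd.Series, trait_col: str,
             covariates: list[str], weights: pd.Series | None = None,
             min_n: int = 50, menopause_imputation_age: float = 50.0,
             ties: str = "efron", robust: bool = True) -> TsriResult:
    """Point estimate of the causal log HR per trait unit.

    ``scores`` maps person -> scaled genetic score; ``covariates`` are the
    stage-1 and stage-2 adjustment set (principal components, birth cohort,
    country, mutation status). ``weights`` are kin-cohort weights for the
    stage-2 Cox model. If stage one fits the trait exactly the residual is
    identically zero and stage two reduces to the plain Cox model on the
    trait (the residual column is dropped rather than entering as a
    constant).
    """
    df = _prepare(pheno, scores, trait_col, min_n)
    Z, _ = design_matrix(df, ["_gs"] + covariates)
    if np.ptp(Z[:, 0]) == 0:
        raise TsriError("genetic score is constant (degenerate instrument)")
    y = df[trait_col].to_numpy(float)
    s1 = sm.OLS(y, sm.add_constant(Z)).fit()
    resid = y - s1.fittedvalues
    f_stat = float(s1.tvalues[1] ** 2)
    if s1.params[1] == 0 or not np.isfinite(f_stat):
        raise TsriError("score explains no trait variance in stage 1")
    zero_resid = resid.std() <= 1e-10 * max(1.0, y.std())
    df["_resid"] = resid
    eps = split_episodes(df, menopause_imputation_age)
    stage2_covs = [trait_col] + ([] if zero_resid else ["_resid"]) + covariates
    res2 = fit_weighted_cox(eps, stage2_covs, weights=weights,
                            cluster="family", ties=ties)
    t = res2.terms.loc[trait_col]
    se = float(t["robust_se"] if robust else t["naive_se"])
    return TsriResult(
        beta=float(t["coef"]),
        naive_se=se,
        p=wald_p(float(t["coef"]), se),
        stage1_coef_gs=float(s1.params[1]),
        stage1_f=f_stat,
        stage1_r2=float(s1.rsquared),
        n=int(len(df)),
        n_events=res2.n_events,
    )


class _BootWorkspace:
    """Precomputed design arrays for fast cluster-bootstrap replicates.

    Dummy coding is fixed once on the full estimation sample, so every
    replicate uses the same columns; per replicate only row indices are
    assembled and the two stages refitted on numpy arrays.
    """

    def __init__(self, pheno, scores, trait_col, covariates, weights,
                 min_n, menopause_imputation_age, resample):
        df = _prepare(pheno, scores, trait_col, min_n)
        self.df = df
        Z, _ = design_matrix(df, ["_gs"] + covariates)
        self.Z1 = np.column_stack([np.ones(len(df)), Z])
        self.y = df[trait_col].to_numpy(float)
        eps = split_episodes(df, menopause_imputation_age)
        X2, names2 = design_matrix(eps, [trait_col] + covariates)
        self.X2 = X2
        self.i_trait = names2.index(trait_col)
        self.start = eps["start"].to_numpy(float)
        self.stop = eps["stop"].to_numpy(float)
        self.event = eps["event"].to_numpy()
        if weights is not None:
            self.w_ep = eps["person"].map(weights).to_numpy(float)
        else:
            self.w_ep = None
        # episode rows per person (episodes are sorted by person)
        persons = df["person"].to_numpy()
        pos = {p: i for i, p in enumerate(persons)}
        ep_person = np.fromiter((pos[p] for p in eps["person"]), int,
                                count=len(eps))
        order = np.argsort(ep_person, kind="stable")
        self.ep_order = order
        sorted_person = ep_person[order]
        firsts = np.searchsorted(sorted_person, np.arange(len(df)))
        self.ep_lo = firsts
        self.ep_hi = np.append(firsts[1:], len(eps))
        unit = df["family"] if resample == "family" else df["person"]
        self.unit_rows = [idx.to_numpy() for _, idx in
                          df.groupby(unit, sort=True).groups.items()]

    def replicate(self, rng, ties):
        draw = rng.integers(0, len(self.unit_rows), size=len(self.unit_rows))
        rows = [self.unit_rows[u] for u in draw]
        pi = np.concatenate(rows)
        Z1r = self.Z1[pi]
        yr = self.y[pi]
        coef, *_ = np.linalg.lstsq(Z1r, yr, rcond=None)
        resid = yr - Z1r @ coef
        # episode rows of each sampled person, cluster = draw index
        counts = np.fromiter((self.ep_hi[p] - self.ep_lo[p] for p in pi),
                             int, count=pi.size)
        ep_rows = self.ep_order[
            np.concatenate([np.arange(self.ep_lo[p], self.ep_hi[p])
                            for p in pi])
        ]
        X = np.column_stack([self.X2[ep_rows], np.repeat(resid, counts)])
        clus = np.repeat(
            np.concatenate([np.full(len(r), i) for i, r in enumerate(rows)]),
            counts,
        )
        w = self.w_ep[ep_rows] if self.w_ep is not None else None
        fit = cox.fit_cox(
            X, self.start[ep_rows], self.stop[ep_rows], self.event[ep_rows],
            weights=w, clusters=clus, ties=ties,
        )
        return float(fit.coef[self.i_trait])


def bootstrap_ci(pheno: pd.DataFrame, scores: pd.Series, trait_col: str,
                 covariates: list[str], b: int, seed: int,
                 weights: pd.Series | None = None,
                 resample: str = "family", max_fail_frac: float = 0.10,
                 min_n: int = 50, menopause_imputation_age: float = 50.0,
                 ties: str = "efron") -> TsriResult:
    """Percentile bootstrap CI for the TSRI estimate.

    The resampling unit is the family (all members kept together), matching
    the family-clustered variance used elsewhere; ``resample="person"``
    switches to individual resampling. The same seed reproduces the CI
    exactly. Replicates whose stage-2 fit fails are counted; more than
    ``max_fail_frac`` failures aborts.
    """
    if b < 2:
        raise TsriError("bootstrap needs B >= 2")
    if resample not in ("family", "person"):
        raise TsriError(f"unknown resampling unit {resample!r}")
    point = tsri_fit(pheno, scores, trait_col, covariates, weights=weights,
                     min_n=min_n,
                     menopause_imputation_age=menopause_imputation_age,
                     ties=ties)
    ws = _BootWorkspace(pheno, scores, trait_col, covariates, weights,
                        min_n, menopause_imputation_age, resample)
    rng = np.random.default_rng(seed)
    estimates = []
    failures = 0
    for _ in range(b):
        try:
            estimates.append(ws.replicate(rng, ties))
        except (cox.CoxError, np.linalg.LinAlgError):
            failures += 1
    if failures > max_fail_frac * b:
        raise TsriError(f"{failures}/{b} bootstrap replicates failed")
    est = np.sort(np.asarray(estimates))
    # inverted-CDF quantiles: with B = 2 the CI is the ordered pair itself
    lo = np.quantile(est, 0.025, method="inverted_cdf")
    hi = np.quantile(est, 0.975, method="inverted_cdf")
    point.boot_b = int(b)
    point.ci_lo = float(lo)
    point.ci_hi = float(hi)
    point.boot_sd = float(est.std(ddof=1))
    point.boot_failures = int(failures)
    point.seed = int(seed)
    return point
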