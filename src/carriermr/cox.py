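"""Weighted Cox proportional-hazards engine on counting-process data.

This is the numerical core of the package: a Newton–Raphson maximiser of the
case-weighted Cox partial likelihood for (start, stop, event] episode data
with age as the timescale, supporting

* left truncation (risk sets are ``{i : start_i < t <= stop_i}``),
* per-episode case weights (kin-cohort / ascertainment weights),
* Efron (default) and Breslow handling of tied event times, and
* a cluster-robust sandwich covariance built from score residuals
  aggregated within clusters (families).

The implementation is fully vectorised over event times; tied event times are
expanded into Efron "steps" so that the no-ties case falls out as a special
case with one step per event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg


class CoxError(RuntimeError):
    """Base class for fitter failures."""


class CollinearityError(CoxError):
    """Design matrix is (numerically) rank deficient."""


class ConvergenceError(CoxError):
    """Newton iterations failed to converge (possible separation)."""


@dataclass
class CoxFit:
    """Fitted weighted Cox model.

    ``coef`` is the log hazard ratio per unit of each column of the design
    matrix; ``robust_cov`` is the cluster-robust sandwich covariance and
    ``naive_cov`` the inverse observed information.
    """

    coef: np.ndarray
    naive_cov: np.ndarray
    robust_cov: np.ndarray
    loglik: float
    n_obs: int
    n_events: int
    n_clusters: int
    ties: str
    n_iter: int
    max_abs_score: float
    converged: bool
    names: list = field(default_factory=list)

    @property
    def naive_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.naive_cov))

    @property
    def robust_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.robust_cov))


def _as_2d(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def _check_design(Xc: np.ndarray, cond_tol: float = 1e-10) -> None:
    """Reject constant or collinear covariates.

    ``Xc`` is the (weighted-)centred design; the check is on the ratio of
    smallest to largest singular value of the column-scaled matrix.
    """
    sd = Xc.std(axis=0)
    if np.any(sd == 0):
        bad = [i for i, s in enumerate(sd) if s == 0]
        raise CollinearityError(f"constant covariate column(s): {bad}")
    # gesvd is slower but does not fail to converge on near-degenerate input
    s = scipy.linalg.svd(Xc / sd, compute_uv=False, lapack_driver="gesvd")
    if s[-1] <= cond_tol * s[0]:
        raise CollinearityError(
            "collinear design matrix (condition number "
            f"{s[0] / max(s[-1], 1e-300):.3g})"
        )


class _Steps:
    """Efron step bookkeeping, independent of beta.

    Each distinct event time with d tied events contributes d steps
    l = 0..d-1; the risk-set denominator at step l is
    ``S0_R - (l/d) * S0_D``.
    """

    def __init__(self, stop, event, weights):
        ev = np.flatnonzero(event)
        if ev.size == 0:
            raise CoxError("no events in data")
        order = ev[np.argsort(stop[ev], kind="stable")]
        self.ev_rows = order                     # event rows sorted by time
        t = stop[order]
        # tie-group boundaries
        uniq, first = np.unique(t, return_index=True)
        self.group_times = uniq                  # K distinct event times
        self.group_start = first                 # index into ev_rows
        d = np.diff(np.append(first, t.size))
        self.group_size = d                      # deaths per group
        self.ev_group = np.repeat(np.arange(uniq.size), d)
        self.W = np.add.reduceat(weights[order], first)  # weighted deaths
        # expand into steps
        self.step_group = np.repeat(np.arange(uniq.size), d)
        self.step_frac = (
            np.concatenate([np.arange(k) for k in d]).astype(float)
            / np.repeat(d, d)
        )
        self.step_time = np.repeat(uniq, d)
        self.step_wd = np.repeat(self.W / d, d)
        # reduceat boundaries for steps of each group
        self.step_first = np.append(0, np.cumsum(d))[:-1]


def _suffix_lookup(sorted_vals, suffix, times, side):
    """Sum over rows with key >= t (strict per ``side``) for each t."""
    idx = np.searchsorted(sorted_vals, times, side=side)
    return suffix[idx]


def fit_cox(
    X,
    start,
    stop,
    event,
    weights=None,
    clusters=None,
    ties: str = "efron",
    max_iter: int = 100,
    tol: float = 1e-10,
    names=None,
) -> CoxFit:
    """Maximise the weighted Cox partial likelihood.

    Parameters
    ----------
    X : (n, p) design matrix (episodes x covariates).
    start, stop : episode boundaries on the age timescale, ``start < stop``.
    event : 1 if the episode ends in the event of interest.
    weights : positive case weights (default all 1).
    clusters : cluster labels for the sandwich variance (default: each
        episode its own cluster; pass person or family ids for dependence).
    ties : ``"efron"`` (default) or ``"breslow"``.

    Returns
    -------
    CoxFit with coefficients, naive and cluster-robust covariance.
    """
    X = _as_2d(X)
    n, p = X.shape
    start = np.asarray(start, dtype=float)
    stop = np.asarray(stop, dtype=float)
    event = np.asarray(event).astype(bool)
    if weights is None:
        weights = np.ones(n)
    else:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights <= 0):
            raise CoxError("weights must be positive")
    if clusters is None:
        clusters = np.arange(n)
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    if np.any(start >= stop):
        raise CoxError("episodes must satisfy start < stop")

    # centre (partial-likelihood invariance) and scale covariates to unit SD
    # for Newton stability; coefficients are mapped back at the end
    xbar = np.average(X, axis=0, weights=weights)
    Xc = X - xbar
    _check_design(Xc)
    x_sd = Xc.std(axis=0)
    Xc = Xc / x_sd

    steps = _Steps(stop, event, weights)
    if ties == "breslow":
        steps.step_frac = np.zeros_like(steps.step_frac)

    # sort orders for suffix sums over stop (risk entry) and start (truncation)
    o_stop = np.argsort(stop, kind="stable")
    stop_sorted = stop[o_stop]
    o_start = np.argsort(start, kind="stable")
    start_sorted = start[o_start]

    ev_rows = steps.ev_rows
    w_ev = weights[ev_rows]
    x_ev = Xc[ev_rows]
    sum_wx_ev = w_ev @ x_ev  # constant part of the score

    XX = np.einsum("ni,nj->nij", Xc, Xc).reshape(n, p * p)

    def suffix(values, order):
        """Suffix sums of ``values`` over the given sort order, with a
        trailing zero row so that out-of-range lookups return 0."""
        v = np.atleast_2d(values[order].T).T
        out = np.zeros((n + 1, v.shape[1]))
        out[:-1] = np.cumsum(v[::-1], axis=0)[::-1]
        return out

    t_g = steps.group_times
    first = steps.group_start

    def group_state(beta):
        """Risk-set sums S0/S1/S2 per distinct event time and per step."""
        eta = Xc @ beta
        if np.max(np.abs(eta)) > 200:
            raise CoxError("linear predictor overflow")
        r = weights * np.exp(eta)
        rX = r[:, None] * Xc
        rXX = r[:, None] * XX
        s0 = suffix(r, o_stop)
        s1 = suffix(rX, o_stop)
        s2 = suffix(rXX, o_stop)
        s0t = suffix(r, o_start)
        s1t = suffix(rX, o_start)
        s2t = suffix(rXX, o_start)
        # risk set {start < t <= stop}: rows with stop >= t minus start >= t
        i_stop = np.searchsorted(stop_sorted, t_g, side="left")
        i_start = np.searchsorted(start_sorted, t_g, side="left")
        S0R = s0[i_stop, 0] - s0t[i_start, 0]
        S1R = s1[i_stop] - s1t[i_start]
        S2R = s2[i_stop] - s2t[i_start]
        # tied-death sums per group
        r_ev = r[ev_rows]
        S0D = np.add.reduceat(r_ev, first)
        S1D = np.add.reduceat(rX[ev_rows], first, axis=0)
        S2D = np.add.reduceat(rXX[ev_rows], first, axis=0)
        g = steps.step_group
        f = steps.step_frac
        phi = S0R[g] - f * S0D[g]
        if np.any(phi <= 0):
            raise CoxError("non-positive risk-set mass (check data)")
        xb = (S1R[g] - f[:, None] * S1D[g]) / phi[:, None]
        x2 = (S2R[g] - f[:, None] * S2D[g]) / phi[:, None]
        return r, phi, xb, x2

    def loglik_parts(beta, phi):
        return float(w_ev @ (x_ev @ beta) - steps.step_wd @ np.log(phi))

    beta = np.zeros(p)
    r, phi, xb, x2 = group_state(beta)
    ll = loglik_parts(beta, phi)
    n_iter = 0
    converged = False
    wd = steps.step_wd
    for n_iter in range(1, max_iter + 1):
        U = sum_wx_ev - wd @ xb
        V = (wd[:, None] * x2).sum(axis=0).reshape(p, p)
        V -= np.einsum("s,si,sj->ij", wd, xb, xb)
        try:
            delta = np.linalg.solve(V, U)
        except np.linalg.LinAlgError as e:  # pragma: no cover
            raise ConvergenceError(f"singular information matrix: {e}") from e
        big = np.max(np.abs(delta))
        if big > 10:  # trust region on the standardized scale
            delta *= 10 / big
        step_scale = 1.0
        for _ in range(40):
            cand = beta + step_scale * delta
            try:
                r2_, phi2, xb2, x22 = group_state(cand)
                ll2 = loglik_parts(cand, phi2)
            except (CoxError, FloatingPointError, OverflowError):
                ll2 = -np.inf
            if np.isfinite(ll2) and ll2 >= ll - 1e-12 * (abs(ll) + 1):
                break
            step_scale /= 2.0
        else:
            raise ConvergenceError(
                f"step-halving failed at iteration {n_iter}; |U|={np.abs(U).max():.3g}"
            )
        moved = np.max(np.abs(cand - beta))
        beta, r, phi, xb, x2, ll = cand, r2_, phi2, xb2, x22, ll2
        # a coefficient of 30 per covariate SD signals monotone likelihood
        if np.max(np.abs(beta)) > 30 or np.max(np.abs(Xc @ beta)) > 500:
            raise ConvergenceError(
                "diverging coefficient (monotone likelihood / separation?)"
            )
        if moved < tol:
            converged = True
            break
    U = sum_wx_ev - wd @ xb
    max_abs_score = float(np.abs(U).max())
    if not converged and max_abs_score > 1e-4 * (1 + abs(ll)):
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations; |U|={max_abs_score:.3g}"
        )
    V = (wd[:, None] * x2).sum(axis=0).reshape(p, p)
    V -= np.einsum("s,si,sj->ij", wd, xb, xb)
    naive_cov = np.linalg.inv(V)

    robust_cov = _sandwich(
        Xc, start, stop, weights, clusters, beta, r, phi, xb, steps, naive_cov
    )

    # back to the original covariate scale
    D = 1.0 / x_sd
    beta = beta * D
    naive_cov = naive_cov * np.outer(D, D)
    robust_cov = robust_cov * np.outer(D, D)

    return CoxFit(
        coef=beta,
        naive_cov=naive_cov,
        robust_cov=robust_cov,
        loglik=ll,
        n_obs=n,
        n_events=int(steps.ev_rows.size),
        n_clusters=int(np.unique(np.asarray(clusters)).size),
        ties=ties,
        n_iter=n_iter,
        max_abs_score=max_abs_score,
        converged=True,
        names=list(names) if names is not None else [f"x{i}" for i in range(p)],
    )


def _sandwich(Xc, start, stop, weights, clusters, beta, r, phi, xb, steps, naive_cov):
    """Cluster-robust covariance from Efron/Breslow score residuals.

    The per-episode score residual decomposes the score U = sum_i U_i at the
    MLE; residuals are summed within clusters, and the sandwich is
    ``A^{-1} B A^{-1}`` with B the outer-product sum of cluster scores.
    """
    n, p = Xc.shape
    wd = steps.step_wd
    f = steps.step_frac
    t_s = steps.step_time
    dphi = wd / phi
    # cumulative hazard-like sums over steps (ascending in time; step order
    # within a tie group does not matter for the window sums)
    cumA = np.append(0.0, np.cumsum(dphi))
    cumB = np.vstack([np.zeros(p), np.cumsum(dphi[:, None] * xb, axis=0)])
    hi = np.searchsorted(t_s, stop, side="right")
    lo = np.searchsorted(t_s, start, side="right")
    A = cumA[hi] - cumA[lo]
    B = cumB[hi] - cumB[lo]
    U = -(r[:, None]) * (A[:, None] * Xc - B)
    # event terms per tie group
    ev_rows = steps.ev_rows
    first = steps.step_first
    d = steps.group_size
    mean_xb = np.add.reduceat(xb, first, axis=0) / d[:, None]
    C1 = np.add.reduceat(f * dphi, first)                       # scalar per group
    C2 = np.add.reduceat((f * dphi)[:, None] * xb, first, axis=0)
    g = steps.ev_group
    w_ev = weights[ev_rows]
    U[ev_rows] += w_ev[:, None] * (Xc[ev_rows] - mean_xb[g])
    # deaths were subtracted with c=1 in the base term; Efron downweights the
    # death's own later steps by (1 - l/d), so add back the l/d portion
    U[ev_rows] += r[ev_rows, None] * (C1[g, None] * Xc[ev_rows] - C2[g])

    codes = np.unique(np.asarray(clusters), return_inverse=True)[1]
    G = np.zeros((codes.max() + 1, p))
    np.add.at(G, codes, U)
    Bmat = G.T @ G
    return naive_cov @ Bmat @ naive_cov
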