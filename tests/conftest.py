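"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pandas as pd
import pytest

from carriermr.simulate import SimConfig, simulate_cohort


# ---------------------------------------------------------------------------
# brute-force weighted Cox partial likelihood (independent of carriermr.cox)
# ---------------------------------------------------------------------------

def brute_loglik(beta, X, start, stop, event, weights=None, ties="efron"):
    """Direct double-loop evaluation of the weighted Cox partial
    log-likelihood for counting-process data."""
    X = np.atleast_2d(np.asarray(X, float).T).T
    beta = np.atleast_1d(np.asarray(beta, float))
    n = X.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    eta = X @ beta
    ll = 0.0
    for t in np.unique(np.asarray(stop)[np.asarray(event, bool)]):
        deaths = [i for i in range(n) if event[i] and stop[i] == t]
        risk = [i for i in range(n) if start[i] < t <= stop[i]]
        s0_r = sum(w[i] * np.exp(eta[i]) for i in risk)
        s0_d = sum(w[i] * np.exp(eta[i]) for i in deaths)
        wd = sum(w[i] for i in deaths)
        d = len(deaths)
        ll += sum(w[i] * eta[i] for i in deaths)
        for ell in range(d):
            frac = ell / d if ties == "efron" else 0.0
            ll -= (wd / d) * np.log(s0_r - frac * s0_d)
    return ll


def brute_fit(X, start, stop, event, weights=None, ties="efron", p=None):
    """Maximise ``brute_loglik`` with scipy (Nelder-Mead polish after BFGS);
    completely independent of the package's Newton implementation."""
    from scipy.optimize import minimize

    X = np.atleast_2d(np.asarray(X, float).T).T
    p = X.shape[1] if p is None else p
    obj = lambda b: -brute_loglik(b, X, start, stop, event, weights, ties)
    res = minimize(obj, np.zeros(p), method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 500})
    res = minimize(obj, res.x, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000})
    return res.x, -res.fun


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_cohort():
    """~1700-person null-effect cohort reused by several modules."""
    return simulate_cohort(SimConfig(n_families=1000, n_snps=40, seed=101))


@pytest.fixture(scope="session")
def causal_cohort():
    """Moderate cohort with a known causal effect and full trait
    measurement, for recovery checks."""
    cfg = SimConfig(n_families=3000, n_snps=40, seed=202,
                    causal_log_hr_per_unit=0.04, missing_trait_fraction=0.0)
    return simulate_cohort(cfg)


@pytest.fixture()
def toy_pheno():
    """Six-person hand-checkable phenotype table (no genotypes)."""
    return pd.DataFrame(
        {
            "person": [f"P{i}" for i in range(6)],
            "family": ["F0", "F0", "F1", "F2", "F3", "F4"],
            "gene": ["BRCA1", "BRCA1", "BRCA2", "BRCA1", "BRCA2", "BRCA1"],
            "birth_year": [1950, 1952, 1960, 1945, 1970, 1955],
            "country": ["UK", "UK", "NL", "USA", "UK", "NL"],
            **{f"pc{i}": np.linspace(-1, 1, 6) for i in range(1, 9)},
            "case": [1, 0, 1, 0, 0, 1],
            "age_ovca": [52.0, np.nan, 45.0, np.nan, np.nan, 61.0],
            "age_breast": [np.nan] * 6,
            "age_rrso": [np.nan, np.nan, np.nan, 47.0, np.nan, np.nan],
            "age_death": [np.nan] * 6,
            "age_end_followup": [np.nan, 60.0, np.nan, np.nan, 38.0, np.nan],
            "age_menopause_natural": [48.0, 51.0, np.nan, np.nan, np.nan, 49.0],
            "height_cm": [167.0, 165.0, 166.0, 170.0, 162.0, 168.0],
            "bmi_now": [24.0, 27.0, 22.0, 30.0, 25.0, 21.0],
            "bmi_young": [21.0, 23.0, 20.0, 26.0, 22.0, 19.5],
            "parity": [2, 0, 1, 3, 0, 2],
            "age_menarche": [13.0, 12.5, 14.0, 13.5, 12.0, 13.0],
            "histology": ["serous", None, "endometrioid", None, None, "serous"],
            "grade": ["poor/undiff", None, "well", None, None, "moderate"],
        }
    )
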