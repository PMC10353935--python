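"""Variance explained: Nagelkerke delta-R2 and its liability-scale transform.

Nagelkerke R2 for a model M against the intercept-only null:

    R2 = (1 - exp((2/n) (logL0 - logLM))) / (1 - exp((2/n) logL0))

The delta is R2(full) - R2(baseline covariates).  The liability-scale
transform is the ascertained case-control correction of Lee et al.
(population prevalence K, sample case fraction P):

    t = Phi^-1(1 - K); z = phi(t); m = z / K; u = m (P - K)/(1 - K)
    theta = u (u - t)
    C = K^2 (1 - K)^2 / (z^2 P (1 - P))
    R2_liab = R2_obs C / (1 + R2_obs theta C)
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from polymix.mix.glmfit import logit_fit

__all__ = ["nagelkerke_r2", "delta_nagelkerke_r2", "liability_r2"]


def _null_llf(y: np.ndarray) -> float:
    n = len(y)
    k = y.sum()
    p = k / n
    if p in (0.0, 1.0):
        return 0.0
    return float(k * np.log(p) + (n - k) * np.log(1 - p))


def nagelkerke_r2(llf_model: float, llf_null: float, n: int) -> float:
    cs = 1.0 - np.exp((2.0 / n) * (llf_null - llf_model))
    denom = 1.0 - np.exp((2.0 / n) * llf_null)
    return float(cs / denom)


def delta_nagelkerke_r2(
    score: np.ndarray,
    cohort,
    outcome_col: str = "prevalent_case",
    covariates: pd.DataFrame | None = None,
) -> float:
    """Nagelkerke R2 of covariates+score minus covariates alone."""
    covs = covariates if covariates is not None else cohort.covariate_matrix()
    covs = covs.reset_index(drop=True)
    y = cohort.data[outcome_col].to_numpy()
    n = len(y)
    llf0 = _null_llf(y)
    base = logit_fit(covs, y)
    full_design = covs.copy()
    full_design["score"] = np.asarray(score, dtype=float)
    full = logit_fit(full_design, y)
    return nagelkerke_r2(full.llf, llf0, n) - nagelkerke_r2(base.llf, llf0, n)


def liability_r2(delta_r2_obs: float, prevalence_K: float, case_fraction_P: float) -> float:
    """Observed-scale delta-R2 mapped to the logit-liability scale."""
    K, P = float(prevalence_K), float(case_fraction_P)
    if not 0.0 < K < 1.0:
        raise ValueError(f"prevalence K must lie in (0, 1), got {K}")
    if not 0.0 < P < 1.0:
        raise ValueError(f"case fraction P must lie in (0, 1), got {P}")
    t = norm.ppf(1.0 - K)
    z = norm.pdf(t)
    m = z / K
    u = m * (P - K) / (1.0 - K)
    theta = u * (u - t)
    c = (K * (1.0 - K)) ** 2 / (z * z * P * (1.0 - P))
    r = float(delta_r2_obs)
    return r * c / (1.0 + r * theta * c)


def liability_r2_from_cohort(
    score: np.ndarray,
    cohort,
    prevalence_K: float,
    outcome_col: str = "prevalent_case",
    covariates: pd.DataFrame | None = None,
) -> float:
    """Convenience: delta Nagelkerke R2 then liability transform, P from the cohort."""
    d = delta_nagelkerke_r2(score, cohort, outcome_col=outcome_col, covariates=covariates)
    p_case = float(cohort.data[outcome_col].mean())
    return liability_r2(d, prevalence_K, p_case)
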