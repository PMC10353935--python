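"""Per-SD association effect sizes: logistic OR and Cox HR.

Both models adjust for the baseline covariates (age, sex, genotyping
array, ten PCs) unless an explicit covariate frame is supplied.  Cox
fits use lifelines with Efron tie handling; incident analyses exclude
prevalent cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy.stats import norm

from polymix.mix.glmfit import logit_fit

__all__ = ["AssocResult", "odds_per_sd", "hazard_per_sd"]


@dataclass
class AssocResult:
    estimate: float  # OR/SD or HR/SD
    ci_low: float
    ci_high: float
    p: float
    log_estimate: float
    se: float
    n: int
    n_events: int

    def validate(self) -> None:
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("confidence interval must contain the point estimate")


def _covariates(cohort, covariates: pd.DataFrame | None) -> pd.DataFrame:
    covs = covariates if covariates is not None else cohort.covariate_matrix()
    return drop_constant_columns(covs)


def drop_constant_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Remove zero-variance columns (all-zero padded PCs in tiny fixtures)."""
    keep = [c for c in df.columns if df[c].nunique(dropna=False) > 1]
    return df[keep]


def odds_per_sd(
    score: np.ndarray,
    cohort,
    outcome_col: str = "prevalent_case",
    covariates: pd.DataFrame | None = None,
) -> AssocResult:
    """Odds ratio per SD of score from a covariate-adjusted logistic model."""
    score = np.asarray(score, dtype=float)
    if score.std() < 1e-12:
        raise ValueError("score has zero variance")
    covs = _covariates(cohort, covariates).reset_index(drop=True)
    design = covs.copy()
    design["score"] = score
    y = cohort.data[outcome_col].to_numpy()
    fit = logit_fit(design, y)
    beta = float(fit.params["score"])
    se = float(fit.bse()["score"])
    z = beta / se
    res = AssocResult(
        estimate=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        p=float(2 * norm.sf(abs(z))),
        log_estimate=beta,
        se=se,
        n=len(y),
        n_events=int(y.sum()),
    )
    res.validate()
    return res


def hazard_per_sd(
    score: np.ndarray,
    cohort,
    covariates: pd.DataFrame | None = None,
    exclude_prevalent: bool = True,
) -> AssocResult:
    """Hazard ratio per SD of score from a covariate-adjusted Cox model."""
    score = np.asarray(score, dtype=float)
    data = cohort.data
    mask = np.ones(len(data), dtype=bool)
    if exclude_prevalent:
        mask = (data["prevalent_case"] == 0).to_numpy()
    events = data.loc[mask, "incident_case"].to_numpy()
    if events.sum() == 0:
        raise ValueError("no events: all incident-analysis samples censored")
    covs = _covariates(cohort, covariates).reset_index(drop=True)
    df = covs.loc[mask].copy()
    df["score"] = score[mask]
    df["T"] = data.loc[mask, "follow_up_time"].to_numpy()
    df["E"] = events
    if np.any(df["T"] <= 0):
        raise ValueError("follow-up times must be positive")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="T", event_col="E")
    beta = float(cph.params_["score"])
    se = float(cph.standard_errors_["score"])
    z = beta / se
    res = AssocResult(
        estimate=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        p=float(2 * norm.sf(abs(z))),
        log_estimate=beta,
        se=se,
        n=int(mask.sum()),
        n_events=int(events.sum()),
    )
    res.validate()
    return res
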