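"""Integrated clinical x genetic risk model.

Cox fit of incident events on the standardized score, the clinical
10-year risk (probability scale), their product term and the ten PCs.
Predicted 10-year cumulative incidence is evaluated on a grid of score
percentiles x the four guideline clinical-risk strata (<5%, 5-<7.5%,
7.5-<20%, >=20%), holding the remaining covariates at their means, with
the baseline hazard from the Breslow-type estimator used by lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy.stats import norm

from polymix.evalrisk.percentiles import percentile_ranks

__all__ = ["IntegratedModelResult", "integrated_risk_model", "CLINICAL_STRATA"]

CLINICAL_STRATA = {
    "low": (0.0, 0.05),
    "borderline": (0.05, 0.075),
    "intermediate": (0.075, 0.20),
    "high": (0.20, 1.01),
}


@dataclass
class IntegratedModelResult:
    interaction_coef: float
    interaction_se: float
    interaction_p: float
    interaction_ci: tuple[float, float]
    coefs: pd.Series
    incidence_grid: pd.DataFrame  # columns: percentile, stratum, predicted_10yr_incidence
    model: CoxPHFitter


def integrated_risk_model(
    score: np.ndarray,
    clinical_risk: np.ndarray,
    cohort,
    horizon: float = 10.0,
    percentile_grid: list[int] | None = None,
) -> IntegratedModelResult:
    """Fit the interaction model and predict standardized 10-year incidence."""
    data = cohort.data
    mask = (data["prevalent_case"] == 0).to_numpy()
    score = np.asarray(score, dtype=float)[mask]
    clin = np.asarray(clinical_risk, dtype=float)[mask]
    pcs = cohort.pc_matrix()[mask]

    df = pd.DataFrame({"score": score, "clinical": clin, "interaction": score * clin})
    pc_cols = []
    for i in range(pcs.shape[1]):
        if np.ptp(pcs[:, i]) > 0:
            df[f"PC{i + 1}"] = pcs[:, i]
            pc_cols.append(i)
    df["T"] = data.loc[mask, "follow_up_time"].to_numpy()
    df["E"] = data.loc[mask, "incident_case"].to_numpy()
    if df["E"].sum() == 0:
        raise ValueError("no incident events")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="T", event_col="E")

    beta = float(cph.params_["interaction"])
    se = float(cph.standard_errors_["interaction"])
    z = beta / se
    zq = 1.959963984540054

    pct = percentile_ranks(score)
    if percentile_grid is None:
        percentile_grid = [0, 4, 9, 19, 29, 39, 49, 59, 69, 79, 89, 94, 99]
    pc_means = {f"PC{i + 1}": float(pcs[:, i].mean()) for i in pc_cols}
    # representative score value per percentile bin (its median)
    rows = []
    for name, (lo, hi) in CLINICAL_STRATA.items():
        in_stratum = (clin >= lo) & (clin < hi)
        if not in_stratum.any():
            continue
        clin_val = float(clin[in_stratum].mean())
        for p in percentile_grid:
            sel = pct == p
            s_val = float(np.median(score[sel])) if sel.any() else float(np.quantile(score, (p + 0.5) / 100))
            row = {"score": s_val, "clinical": clin_val, "interaction": s_val * clin_val, **pc_means}
            rows.append({"percentile": p, "stratum": name, "_row": row})
    pred_df = pd.DataFrame([r["_row"] for r in rows])
    surv = cph.predict_survival_function(pred_df, times=[horizon])
    incidence = 1.0 - surv.iloc[0].to_numpy()
    grid = pd.DataFrame(
        {
            "percentile": [r["percentile"] for r in rows],
            "stratum": [r["stratum"] for r in rows],
            "predicted_10yr_incidence": incidence,
        }
    )
    return IntegratedModelResult(
        interaction_coef=beta,
        interaction_se=se,
        interaction_p=float(2 * norm.sf(abs(z))),
        interaction_ci=(beta - zq * se, beta + zq * se),
        coefs=cph.params_.copy(),
        incidence_grid=grid,
        model=cph,
    )
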