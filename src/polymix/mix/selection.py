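"""Candidate tuning and bidirectional stepwise AIC selection."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from polymix.mix.glmfit import logit_fit
from polymix.score.scoring import score_cohort
from polymix.shrink.weights import WeightSet

__all__ = ["tune_best_candidate", "stepwise_aic_select"]

logger = logging.getLogger(__name__)


def tune_best_candidate(
    candidate_weightsets: list[WeightSet],
    training_cohort,
    outcome_col: str = "prevalent_case",
) -> tuple[WeightSet, pd.DataFrame]:
    """Pick the grid candidate maximizing the covariate-adjusted logistic likelihood.

    Every candidate is scored and standardized on the training cohort and
    entered (alone) into ``outcome ~ covariates + score``; the candidate
    with the highest log-likelihood wins, with ties (within 1e-9) broken
    by smaller p, then smaller s, then non-sparse.  Returns the winner and
    a per-candidate summary table.
    """
    if not candidate_weightsets:
        raise ValueError("need at least one candidate weight set")
    covs = training_cohort.covariate_matrix()
    y = training_cohort.data[outcome_col].to_numpy()
    records = []
    fits: list[float | None] = []
    for i, ws in enumerate(candidate_weightsets):
        try:
            sv, _, _ = score_cohort(training_cohort, ws, score_id=f"cand{i}")
        except ValueError as exc:
            logger.info("candidate %d degenerate: %s", i, exc)
            fits.append(None)
            records.append({"candidate": i, "llf": np.nan})
            continue
        design = covs.copy()
        design["score"] = sv.standardized
        fit = logit_fit(design, y)
        fits.append(fit.llf)
        records.append(
            {
                "candidate": i,
                "llf": fit.llf,
                "aic": fit.aic,
                "p": ws.metadata.get("p"),
                "s": ws.metadata.get("s"),
                "sparse": ws.metadata.get("sparse"),
            }
        )
    valid = [i for i, f in enumerate(fits) if f is not None]
    if not valid:
        raise ValueError("all candidate weight sets were degenerate")
    best_llf = max(fits[i] for i in valid)
    contenders = [i for i in valid if fits[i] >= best_llf - 1e-9]
    winner = min(contenders, key=lambda i: candidate_weightsets[i].sort_key())
    return candidate_weightsets[winner], pd.DataFrame(records)


def stepwise_aic_select(
    component_scores: pd.DataFrame,
    outcome: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> tuple[list[str], list[float]]:
    """Bidirectional stepwise AIC on ``outcome ~ covariates + components``.

    Starts from the full model; at each step takes the single add/drop
    move with the largest AIC reduction; stops when no move reduces AIC.
    Returns the selected component names and the AIC trace along accepted
    steps (trace[0] is the full model).
    """
    if component_scores.shape[1] < 1:
        raise ValueError("need at least one component score")
    components = list(component_scores.columns)
    covs = covariates if covariates is not None else pd.DataFrame(index=component_scores.index)

    def fit_aic(included: list[str]) -> float:
        design = pd.concat([covs, component_scores[included]], axis=1)
        if design.shape[1] == 0:
            design = pd.DataFrame(index=component_scores.index)
        return logit_fit(design, outcome).aic

    included = list(components)
    trace = [fit_aic(included)]
    while True:
        moves: list[tuple[float, str, str]] = []
        for c in included:
            trial = [x for x in included if x != c]
            moves.append((fit_aic(trial), "drop", c))
        for c in components:
            if c not in included:
                moves.append((fit_aic(included + [c]), "add", c))
        if not moves:
            break
        best_aic, action, comp = min(moves, key=lambda t: t[0])
        if best_aic < trace[-1] - 1e-10:
            if action == "drop":
                included.remove(comp)
            else:
                included.append(comp)
            trace.append(best_aic)
        else:
            break
    return included, trace
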