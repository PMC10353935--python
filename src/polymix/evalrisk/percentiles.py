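"""Percentile binning, tail odds scans and the risk-equivalence search.

Percentile ranks order by ascending score with ties broken by stable
input order; the "middle quintile" reference is ranks 40-59 inclusive.
Tail and risk-equivalence scans move from the extreme inward over
integer percentile cut-offs and stop at the first failure, adjudicating
by point estimate (not CI bound).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy.stats import beta as beta_dist

from polymix.mix.glmfit import logit_fit

__all__ = [
    "percentile_ranks",
    "percentile_prevalence",
    "tail_fraction_scan",
    "risk_equivalent_threshold",
]

MIDDLE_QUINTILE = (40, 59)


def percentile_ranks(score: np.ndarray) -> np.ndarray:
    """Integer percentile bin (0..99) by ascending score, stable ties."""
    score = np.asarray(score)
    n = len(score)
    order = np.argsort(score, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return np.minimum((ranks * 100) // n, 99)


def percentile_prevalence(score: np.ndarray, outcome: np.ndarray) -> pd.DataFrame:
    """Unadjusted case fraction per percentile bin, with Clopper-Pearson CIs."""
    outcome = np.asarray(outcome)
    if len(outcome) < 100:
        raise ValueError("need at least 100 samples for percentile binning")
    pct = percentile_ranks(score)
    rows = []
    for b in range(100):
        mask = pct == b
        n = int(mask.sum())
        k = int(outcome[mask].sum())
        lo = 0.0 if k == 0 else float(beta_dist.ppf(0.025, k, n - k + 1))
        hi = 1.0 if k == n else float(beta_dist.ppf(0.975, k + 1, n - k))
        rows.append({"percentile": b, "n": n, "cases": k, "prevalence": k / n, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def _middle_mask(pct: np.ndarray) -> np.ndarray:
    return (pct >= MIDDLE_QUINTILE[0]) & (pct <= MIDDLE_QUINTILE[1])


def tail_fraction_scan(
    score: np.ndarray,
    outcome: np.ndarray,
    fold_thresholds: list[float],
    direction: str = "top",
    covariates: pd.DataFrame | None = None,
    max_percentiles: int = 99,
) -> pd.DataFrame:
    """Largest tail fraction whose OR vs the middle quintile meets each threshold.

    For ``direction='top'`` thresholds are fold increases (OR >= f); for
    ``'bottom'`` they are fold decreases given as fractions (OR <= f,
    e.g. 1/3).  Integer cut-offs are scanned from the extreme inward
    (middle-quintile members never enter the tail group); the scan stops
    at the first cut-off whose OR point estimate misses the threshold.
    Returns one row per threshold with the achieved population fraction
    (0 when even the most extreme percentile fails).
    """
    if direction not in ("top", "bottom"):
        raise ValueError("direction must be 'top' or 'bottom'")
    outcome = np.asarray(outcome)
    pct = percentile_ranks(score)
    middle = _middle_mask(pct)
    n = len(outcome)
    rows = []
    for f in fold_thresholds:
        best_frac, best_x, best_or = 0.0, 0, np.nan
        for x in range(1, max_percentiles + 1):
            tail = ((pct >= 100 - x) if direction == "top" else (pct < x)) & ~middle
            if tail.sum() == 0:
                break
            if outcome[tail].sum() == 0:
                if direction == "top":
                    break  # no tail events: OR ~ 0, cannot meet a fold increase
                or_hat = 0.0  # no tail events: passes any fold-decrease threshold
            else:
                sel = tail | middle
                design = pd.DataFrame({"tail": tail[sel].astype(float)})
                if covariates is not None:
                    design = pd.concat(
                        [design.reset_index(drop=True), covariates.loc[sel].reset_index(drop=True)],
                        axis=1,
                    )
                fit = logit_fit(design, outcome[sel])
                or_hat = float(np.exp(fit.params["tail"]))
            ok = or_hat >= f if direction == "top" else or_hat <= f
            if not ok:
                break
            best_frac, best_x, best_or = float(tail.sum()) / n, x, or_hat
        rows.append(
            {
                "threshold": f,
                "direction": direction,
                "percentile_cutoff": best_x,
                "fraction": best_frac,
                "odds_ratio": best_or,
            }
        )
    return pd.DataFrame(rows)


def risk_equivalent_threshold(
    score: np.ndarray,
    cohort,
    comparator_flag: np.ndarray,
    max_percentile: int = 79,
) -> tuple[int | None, pd.DataFrame]:
    """Largest top-x%% whose incident-event HR reaches the comparator group's HR.

    Fits a three-group Cox model (comparator, top-x of comparator-free
    samples, middle-quintile reference) on follow-up events.  Scans x
    from 1 upward; stops at the first x whose top-group HR point estimate
    falls below the comparator HR.  Returns ``(x, trace)`` with ``x``
    None when no percentile qualifies.
    """
    comparator = np.asarray(comparator_flag).astype(bool)
    if comparator.sum() == 0:
        raise ValueError("comparator group is empty")
    data = cohort.data
    time = data["follow_up_time"].to_numpy()
    event = data["event_any"].to_numpy() if "event_any" in data.columns else data["incident_case"].to_numpy()

    free = ~comparator
    pct = np.full(len(data), -1, dtype=np.int64)
    pct[free] = percentile_ranks(np.asarray(score)[free])
    middle = free & (pct >= MIDDLE_QUINTILE[0]) & (pct <= MIDDLE_QUINTILE[1])

    rows = []
    best: int | None = None
    for x in range(1, max_percentile + 1):
        top = free & (pct >= 100 - x) & ~middle
        sel = comparator | top | middle
        df = pd.DataFrame(
            {
                "comparator": comparator[sel].astype(float),
                "top": top[sel].astype(float),
                "T": time[sel],
                "E": event[sel],
            }
        )
        if df["E"].sum() == 0 or top.sum() == 0:
            break
        cph = CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E")
        hr_comp = float(np.exp(cph.params_["comparator"]))
        hr_top = float(np.exp(cph.params_["top"]))
        rows.append({"percentile": x, "hr_top": hr_top, "hr_comparator": hr_comp})
        if hr_top >= hr_comp:
            best = x
        else:
            break
    return best, pd.DataFrame(rows)
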