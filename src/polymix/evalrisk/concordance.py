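"""Harrell's C-statistic with an asymptotic confidence interval.

A pair is usable when censoring lets us order the failures: the earlier
time carries an event, or times tie with exactly one event (the censored
member outlived the case).  Prediction ties count 0.5.  The CI uses a
U-statistic-style variance from per-subject concordance influence terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.stats import norm

__all__ = ["ConcordanceResult", "harrell_c"]


@dataclass
class ConcordanceResult:
    c: float
    ci_low: float
    ci_high: float
    se: float
    n_usable_pairs: int


@njit(cache=True)
def _concordance_counts(pred, time, event):
    n = pred.shape[0]
    conc = np.zeros(n)
    usable = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            if time[i] < time[j]:
                first, second = i, j
            elif time[j] < time[i]:
                first, second = j, i
            else:
                if event[i] == 1 and event[j] == 0:
                    first, second = i, j
                elif event[j] == 1 and event[i] == 0:
                    first, second = j, i
                else:
                    continue
            if event[first] == 0:
                continue
            if pred[first] > pred[second]:
                score = 1.0
            elif pred[first] == pred[second]:
                score = 0.5
            else:
                score = 0.0
            conc[i] += score
            conc[j] += score
            usable[i] += 1.0
            usable[j] += 1.0
    return conc, usable


def harrell_c(risk_predictions: np.ndarray, time: np.ndarray, event: np.ndarray) -> ConcordanceResult:
    """Concordance of predictions (higher = riskier) with observed failure order."""
    pred = np.ascontiguousarray(risk_predictions, dtype=np.float64)
    t = np.ascontiguousarray(time, dtype=np.float64)
    e = np.ascontiguousarray(event, dtype=np.int64)
    if not (pred.shape == t.shape == e.shape):
        raise ValueError("predictions, time and event must have equal length")
    conc, usable = _concordance_counts(pred, t, e)
    total_usable = usable.sum() / 2.0
    if total_usable == 0:
        raise ValueError("no usable pairs (all observations censored or tied)")
    c = float(conc.sum() / 2.0 / total_usable)
    # influence-function variance of the U-statistic ratio
    infl = conc - c * usable
    var = float((infl @ infl) / (4.0 * total_usable**2)) * 4.0
    se = float(np.sqrt(max(var, 0.0)))
    zq = norm.ppf(0.975)
    return ConcordanceResult(
        c=c,
        ci_low=float(max(0.0, c - zq * se)),
        ci_high=float(min(1.0, c + zq * se)),
        se=se,
        n_usable_pairs=int(round(total_usable)),
    )
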