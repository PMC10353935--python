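"""Logistic fitting helper with a ridge fallback under separation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["LogitFit", "logit_fit"]

RIDGE_ALPHA = 1e-6


@dataclass
class LogitFit:
    params: pd.Series
    llf: float
    cov: np.ndarray
    n: int
    ridged: bool = False

    @property
    def k(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.llf

    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)


def _ridge_logit(x: np.ndarray, y: np.ndarray, alpha: float, max_iter: int = 100) -> np.ndarray:
    beta = np.zeros(x.shape[1])
    pen = alpha * np.eye(x.shape[1])
    for _ in range(max_iter):
        eta = np.clip(x @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        grad = x.T @ (y - p) - alpha * beta
        hess = (x * w[:, None]).T @ x + pen
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def logit_fit(design: pd.DataFrame, outcome: np.ndarray, add_intercept: bool = True) -> LogitFit:
    """Fit a logistic regression; on separation fall back to a tiny ridge penalty."""
    x = design.copy()
    if add_intercept:
        x.insert(0, "const", 1.0)
    xm = x.to_numpy(dtype=float)
    y = np.asarray(outcome, dtype=float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, xm).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(res.params)) or np.max(np.abs(res.params)) > 1e3:
            raise np.linalg.LinAlgError("suspected separation")
        return LogitFit(
            params=pd.Series(res.params, index=x.columns),
            llf=float(res.llf),
            cov=np.asarray(res.cov_params()),
            n=len(y),
        )
    except Exception:
        warnings.warn("logistic fit failed to converge cleanly; applying ridge fallback")
        beta = _ridge_logit(xm, y, RIDGE_ALPHA)
        eta = np.clip(xm @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        llf = float(np.sum(y * np.log(np.clip(p, 1e-12, 1)) + (1 - y) * np.log(np.clip(1 - p, 1e-12, 1))))
        w = p * (1.0 - p)
        cov = np.linalg.pinv((xm * w[:, None]).T @ xm + RIDGE_ALPHA * np.eye(xm.shape[1]))
        return LogitFit(params=pd.Series(beta, index=x.columns), llf=llf, cov=cov, n=len(y), ridged=True)
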