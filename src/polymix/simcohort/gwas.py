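"""Per-variant marginal GWAS on a simulated cohort.

Binary traits use per-variant logistic regression (intercept + dosage),
fit by a vectorized Newton-Raphson across variant chunks; quantitative
traits use closed-form simple linear regression.  Monomorphic variants
are flagged missing (NaN beta/se/p), never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["SummaryStats", "run_gwas"]

TSV_COLUMNS = [
    "variant_id",
    "chr",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "p",
    "n",
    "n_cases",
]


@dataclass
class SummaryStats:
    """Marginal GWAS results for one trait in one ancestry."""

    table: pd.DataFrame  # columns TSV_COLUMNS
    trait: str = ""
    ancestry: str = ""

    def __len__(self) -> int:
        return len(self.table)

    def validate(self) -> None:
        missing = [c for c in TSV_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")
        ok = self.table["se"].notna()
        if np.any(self.table.loc[ok, "se"] <= 0):
            raise ValueError("se must be positive where present")
        z = self.table.loc[ok, "beta"] / self.table.loc[ok, "se"]
        p_expect = 2.0 * norm.sf(np.abs(z))
        p_got = self.table.loc[ok, "p"].to_numpy()
        denom = np.maximum(p_expect, 1e-300)
        if np.any(np.abs(p_got - p_expect) / denom > 1e-6):
            raise ValueError("p-values inconsistent with beta/se under normal approximation")
        alleles = set(self.table["effect_allele"]) | set(self.table["other_allele"])
        if not alleles <= {"A", "C", "G", "T"}:
            raise ValueError(f"allele labels outside ACGT: {alleles - set('ACGT')}")

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.table[TSV_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path, trait: str = "", ancestry: str = "") -> "SummaryStats":
        table = pd.read_csv(path, sep="\t", na_values=["NA"])
        return cls(table=table, trait=trait, ancestry=ancestry)


def _linear_gwas(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # sufficient-statistic form: no centered copy of the dosage matrix
    n = g.shape[0]
    gbar = g.mean(axis=0)
    ybar = y.mean()
    sxy = y @ g - n * ybar * gbar
    ssx = np.einsum("ij,ij->j", g, g) - n * gbar * gbar
    beta = np.full(g.shape[1], np.nan)
    se = np.full(g.shape[1], np.nan)
    ok = ssx > 1e-12
    beta[ok] = sxy[ok] / ssx[ok]
    ssy = y @ y - n * ybar * ybar
    resvar = (ssy - beta[ok] ** 2 * ssx[ok]) / (n - 2)
    se[ok] = np.sqrt(np.maximum(resvar, 1e-300) / ssx[ok])
    return beta, se


def _logistic_gwas_chunk(
    g: np.ndarray,
    y: np.ndarray,
    buf: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-10,
):
    """Vectorized Newton for ``y ~ 1 + g_j`` independently over columns of g.

    ``buf`` is an optional (2, n, >=m) scratch array reused across chunks
    (fresh large allocations are expensive on some hosts).
    """
    n, m = g.shape
    if buf is None:
        buf = np.empty((2, n, m))
    eta = buf[0, :, :m]
    wrk = buf[1, :, :m]
    ybar = np.clip(y.mean(), 1e-12, 1 - 1e-12)
    a = np.full(m, np.log(ybar / (1.0 - ybar)))
    b = np.zeros(m)

    def moments():
        # eta <- p (probabilities), wrk <- w * g; returns info sums
        np.multiply(g, b[None, :], out=eta)
        np.add(eta, a[None, :], out=eta)
        np.negative(eta, out=eta)
        np.exp(eta, out=eta)
        np.add(eta, 1.0, out=eta)
        np.reciprocal(eta, out=eta)  # eta is now p
        p = eta
        np.subtract(1.0, p, out=wrk)
        np.multiply(p, wrk, out=wrk)  # wrk is now w = p(1-p)
        saa = wrk.sum(axis=0)
        np.multiply(wrk, g, out=wrk)  # w*g
        sab = wrk.sum(axis=0)
        sbb = np.einsum("ij,ij->j", wrk, g)
        return p, saa, sab, sbb

    for _ in range(max_iter):
        p, saa, sab, sbb = moments()
        ga = y.sum() - p.sum(axis=0)
        gb = y @ g - np.einsum("ij,ij->j", p, g)
        det = saa * sbb - sab * sab
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        da = np.clip((sbb * ga - sab * gb) / det, -5, 5)
        db = np.clip((saa * gb - sab * ga) / det, -5, 5)
        a += da
        b += db
        if max(np.nanmax(np.abs(da)), np.nanmax(np.abs(db))) < tol:
            break
    _, saa, sab, sbb = moments()
    det = saa * sbb - sab * sab
    se_b = np.sqrt(np.where(det > 0, saa / det, np.nan))
    return b, se_b


def run_gwas(cohort, trait: str, model_type: str = "auto", ancestry: str | None = None) -> SummaryStats:
    """One marginal regression per variant of ``trait`` on dosage.

    ``model_type`` is ``"logistic"`` (binary outcome), ``"linear"``
    (quantitative), or ``"auto"``.  ``ancestry`` restricts to one sample
    group.  Deterministic given the cohort.
    """
    data = cohort.data
    mask = np.ones(len(data), dtype=bool)
    if ancestry is not None:
        mask = (data["ancestry"] == ancestry).to_numpy()
    if trait not in data.columns:
        raise ValueError(f"trait {trait!r} not present in cohort")
    y = data.loc[mask, trait].to_numpy(dtype=float)
    g = cohort.dosages if mask.all() else cohort.dosages[mask]
    n = len(y)

    if model_type == "auto":
        model_type = "logistic" if set(np.unique(y)) <= {0.0, 1.0} else "linear"
    if model_type not in ("logistic", "linear"):
        raise ValueError(f"model_type must be 'logistic' or 'linear', got {model_type!r}")

    gbar = g.mean(axis=0)
    mono = np.einsum("ij,ij->j", g, g) / n - gbar * gbar <= 1e-12
    beta = np.full(g.shape[1], np.nan)
    se = np.full(g.shape[1], np.nan)
    poly = ~mono
    if poly.any():
        if model_type == "linear":
            beta[poly], se[poly] = _linear_gwas(g[:, poly], y)
        else:
            cols = np.flatnonzero(poly)
            chunk = 256
            buf = np.empty((2, n, min(chunk, len(cols))))
            for start in range(0, len(cols), chunk):
                idx = cols[start : start + chunk]
                beta[idx], se[idx] = _logistic_gwas_chunk(np.ascontiguousarray(g[:, idx]), y, buf=buf)

    with np.errstate(invalid="ignore", divide="ignore"):
        p = 2.0 * norm.sf(np.abs(beta / se))

    n_cases = int(y.sum()) if model_type == "logistic" else np.nan
    table = pd.DataFrame(
        {
            "variant_id": cohort.variants["variant_id"],
            "chr": cohort.variants["chrom"],
            "pos": cohort.variants["pos"],
            "effect_allele": cohort.variants["effect_allele"],
            "other_allele": cohort.variants["other_allele"],
            "eaf": g.mean(axis=0) / 2.0,
            "beta": beta,
            "se": se,
            "p": p,
            "n": n,
            "n_cases": n_cases,
        }
    )
    out = SummaryStats(table=table, trait=trait, ancestry=ancestry or "ALL")
    out.validate()
    return out
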