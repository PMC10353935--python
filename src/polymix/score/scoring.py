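"""Raw score accumulation and per-ancestry standardization.

Raw score is sum_j dosage_ij * w_j over aligned variants (complemented
dosages contribute ``2 - d``); missing dosages are mean-imputed to 2f
first.  Standardization residualizes the raw score on the first ten PCs
within each ancestry group (OLS with intercept) and z-scales; the
per-group regression coefficients, mean and SD are retained so that a
validation cohort can reuse training-derived constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScoreVector",
    "StandardizationConstants",
    "compute_raw_scores",
    "standardize_scores",
    "score_cohort",
]


@dataclass
class StandardizationConstants:
    """Per-ancestry-group residualization and scaling constants."""

    pc_coefs: dict[str, np.ndarray] = field(default_factory=dict)  # group -> (1 + n_pcs,)
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    def pooled_sd(self) -> float:
        """Sample-size-free summary scale across groups (mean of group SDs)."""
        return float(np.mean(list(self.sd.values())))


@dataclass
class ScoreVector:
    sample_ids: np.ndarray
    raw: np.ndarray
    ancestry: np.ndarray
    standardized: np.ndarray | None = None
    score_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "raw": self.raw,
                "standardized": self.standardized,
                "ancestry": self.ancestry,
                "score_id": self.score_id,
            }
        )


def compute_raw_scores(
    dosages: np.ndarray,
    aligned_weights: pd.DataFrame,
    sample_ids: np.ndarray | None = None,
    ancestry: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
    score_id: str = "",
) -> ScoreVector:
    """Accumulate dosage x weight into per-sample raw scores.

    ``aligned_weights`` comes from :func:`polymix.score.match_alleles`
    (columns variant_index, weight, complement).
    """
    n, m = dosages.shape
    idx = aligned_weights["variant_index"].to_numpy()
    if idx.size and idx.max() >= m:
        raise ValueError("aligned variant index exceeds dosage matrix width")
    w = aligned_weights["weight"].to_numpy(dtype=float)
    comp = aligned_weights["complement"].to_numpy(dtype=bool)

    d = dosages[:, idx]
    if np.isnan(d).any():
        if freqs is None:
            raise ValueError("missing dosages present but no frequencies given for imputation")
        fill = 2.0 * freqs[idx]
        d = np.where(np.isnan(d), fill[None, :], d)
    # complemented variants contribute w * (2 - d) = 2w - w*d
    signed = np.where(comp, -w, w)
    const = 2.0 * w[comp].sum()
    raw = d @ signed + const
    return ScoreVector(
        sample_ids=sample_ids if sample_ids is not None else np.arange(n),
        raw=raw,
        ancestry=ancestry if ancestry is not None else np.repeat("ALL", n),
        score_id=score_id,
    )


def standardize_scores(
    scores: ScoreVector,
    pcs: np.ndarray,
    ancestry_labels: np.ndarray | None = None,
    constants: StandardizationConstants | None = None,
    min_group_size: int = 30,
) -> tuple[ScoreVector, StandardizationConstants]:
    """PC-residualize and z-scale raw scores within each ancestry group.

    When ``constants`` is provided (a training-cohort fit), its
    coefficients, means and SDs are applied instead of refitting, which
    prevents leakage into validation cohorts.
    """
    labels = ancestry_labels if ancestry_labels is not None else scores.ancestry
    labels = np.asarray(labels)
    raw = scores.raw
    out = np.empty_like(raw, dtype=float)
    fitting = constants is None
    consts = constants or StandardizationConstants()

    for group in np.unique(labels):
        mask = labels == group
        x = np.column_stack([np.ones(mask.sum()), pcs[mask]])
        y = raw[mask]
        if fitting:
            if mask.sum() < min_group_size:
                raise ValueError(f"ancestry group {group!r} has fewer than {min_group_size} samples")
            rank = np.linalg.matrix_rank(x)
            if rank < x.shape[1]:
                warnings.warn(f"collinear PC columns in group {group!r}; using least-norm fit")
            coef, *_ = np.linalg.lstsq(x, y, rcond=None)
            resid = y - x @ coef
            mu, sd = float(resid.mean()), float(resid.std())
            if sd < 1e-12:
                raise ValueError(f"zero residual variance for group {group!r}")
            consts.pc_coefs[group] = coef
            consts.mean[group] = mu
            consts.sd[group] = sd
        else:
            if group not in consts.pc_coefs:
                raise ValueError(f"no training constants for ancestry group {group!r}")
            coef, mu, sd = consts.pc_coefs[group], consts.mean[group], consts.sd[group]
            resid = y - x @ coef
        out[mask] = (resid - mu) / sd

    result = ScoreVector(
        sample_ids=scores.sample_ids,
        raw=raw,
        ancestry=labels,
        standardized=out,
        score_id=scores.score_id,
    )
    return result, consts


def score_cohort(
    cohort,
    weightset,
    constants: StandardizationConstants | None = None,
    score_id: str | None = None,
):
    """Match, accumulate and standardize one WeightSet on a Cohort.

    Returns ``(ScoreVector, StandardizationConstants, MatchReport)``.
    """
    from polymix.score.matching import match_alleles

    aligned, report = match_alleles(weightset, cohort.variants)
    sv = compute_raw_scores(
        cohort.dosages,
        aligned,
        sample_ids=cohort.data["sample_id"].to_numpy(),
        ancestry=cohort.data["ancestry"].to_numpy(),
        freqs=cohort.variants["freq"].to_numpy(),
        score_id=score_id or weightset.metadata.get("trait", "score"),
    )
    sv, consts = standardize_scores(sv, cohort.pc_matrix(), constants=constants)
    return sv, consts, report
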