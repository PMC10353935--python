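"""Heritability from summary statistics by LD-score regression.

Per-variant LD scores are the sum of squared within-block correlations
from the reference panel.  Under the polygenic model
``E[chi2_j] = 1 + N * h2 * l_j / M``, regressing chi-square statistics
on LD scores gives a slope that rescales to h2; the intercept captures
confounding-like inflation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from polymix.simcohort.gwas import SummaryStats
from polymix.simcohort.ldpanel import LDPanel

__all__ = ["HeritabilityEstimate", "estimate_heritability_ldsc"]

MIN_VARIANTS = 200
H2_CLIP = (1e-4, 0.99)


@dataclass
class HeritabilityEstimate:
    h2_hat: float
    intercept: float
    se: float

    @property
    def h2_clipped(self) -> float:
        """Value safe for use as a prior parameter."""
        return float(np.clip(self.h2_hat, *H2_CLIP))


def estimate_heritability_ldsc(sumstats: SummaryStats, panel: LDPanel) -> HeritabilityEstimate:
    """Regress chi-square statistics on panel LD scores to estimate h2."""
    ld = pd.DataFrame({"variant_id": panel.variant_ids, "ldscore": panel.ld_scores()})
    tab = sumstats.table.merge(ld, on="variant_id", how="inner")
    tab = tab[tab["beta"].notna() & tab["se"].notna()]
    if len(tab) < MIN_VARIANTS:
        raise ValueError(
            f"heritability estimation needs >= {MIN_VARIANTS} variants with "
            f"non-missing statistics, got {len(tab)}"
        )
    z = tab["beta"].to_numpy() / tab["se"].to_numpy()
    chi2 = z * z
    ell = tab["ldscore"].to_numpy()
    n_mean = float(tab["n"].mean())
    m = len(tab)

    x = np.column_stack([np.ones(m), ell])
    coef, *_ = np.linalg.lstsq(x, chi2, rcond=None)
    resid = chi2 - x @ coef
    dof = max(m - 2, 1)
    cov = np.linalg.inv(x.T @ x) * (resid @ resid / dof)
    slope_se = float(np.sqrt(cov[1, 1]))

    scale = m / n_mean
    return HeritabilityEstimate(
        h2_hat=float(coef[1] * scale), intercept=float(coef[0]), se=slope_se * scale
    )
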