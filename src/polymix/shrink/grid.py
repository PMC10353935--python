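"""Hyperparameter grid enumeration over (p, s, sparse).

The default grid is 17 causal-fraction values, 3 heritability scales and
the sparse on/off flag, giving 102 candidate weight sets per set of
summary statistics.  Each candidate's prior slab variance uses
``h2_prior = s * h2_hat`` with h2_hat from LD-score regression (or a
supplied override).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from polymix._rng import subseed
from polymix.shrink.gibbs import GibbsConfig, posterior_mean_effects
from polymix.shrink.ldsc import estimate_heritability_ldsc
from polymix.shrink.weights import WeightSet
from polymix.simcohort.gwas import SummaryStats
from polymix.simcohort.ldpanel import LDPanel

__all__ = ["GridConfig", "enumerate_grid", "DEFAULT_CAUSAL_FRACTIONS", "DEFAULT_H2_SCALES"]

DEFAULT_CAUSAL_FRACTIONS = [
    1.0e-4, 1.8e-4, 3.2e-4, 5.6e-4,
    1.0e-3, 1.8e-3, 3.2e-3, 5.6e-3,
    1.0e-2, 1.8e-2, 3.2e-2, 5.6e-2,
    1.0e-1, 1.8e-1, 3.2e-1, 5.6e-1,
    1.0,
]
DEFAULT_H2_SCALES = [0.7, 1.0, 1.4]


@dataclass
class GridConfig:
    causal_fractions: list[float] = field(default_factory=lambda: list(DEFAULT_CAUSAL_FRACTIONS))
    h2_scales: list[float] = field(default_factory=lambda: list(DEFAULT_H2_SCALES))
    sparse_flags: list[bool] = field(default_factory=lambda: [False, True])
    gibbs_iterations: int = 500
    burn_in: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.causal_fractions or not self.h2_scales or not self.sparse_flags:
            raise ValueError("grid axes must be non-empty")
        for p in self.causal_fractions:
            if not 0.0 < p <= 1.0:
                raise ValueError(f"causal fraction {p} outside (0, 1]")
        for s in self.h2_scales:
            if s <= 0:
                raise ValueError(f"h2 scale {s} must be > 0")

    @property
    def size(self) -> int:
        return len(self.causal_fractions) * len(self.h2_scales) * len(self.sparse_flags)


def enumerate_grid(
    sumstats: SummaryStats,
    panel: LDPanel,
    grid_config: GridConfig | None = None,
    h2_hat: float | None = None,
) -> list[WeightSet]:
    """One posterior-mean WeightSet per (p, s, sparse) grid combination."""
    cfg = grid_config or GridConfig()
    if h2_hat is None:
        h2_hat = estimate_heritability_ldsc(sumstats, panel).h2_clipped
    out: list[WeightSet] = []
    for p, s, sparse in product(cfg.causal_fractions, cfg.h2_scales, cfg.sparse_flags):
        gc = GibbsConfig(
            iterations=cfg.gibbs_iterations,
            burn_in=cfg.burn_in,
            seed=subseed(cfg.seed, "grid", repr((p, s, sparse))),
        )
        ws = posterior_mean_effects(sumstats, panel, p=p, h2_prior=s * h2_hat, sparse=sparse, gibbs_config=gc)
        ws.metadata.update({"s": float(s), "h2_hat": float(h2_hat)})
        out.append(ws)
    return out
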