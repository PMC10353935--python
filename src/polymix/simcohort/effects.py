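"""Ground-truth causal effects shared across ancestries and traits.

Causal variants are a single Bernoulli(p) draw shared by every ancestry;
their standardized-scale effects are drawn jointly with a Kronecker
(ancestry x trait) correlation structure and then rescaled per
(ancestry, trait) so the genetic variance implied by the ancestry's LD
panel equals the target heritability exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from polymix._rng import substream
from polymix.simcohort.ldpanel import LDPanel

__all__ = ["TrueEffectSet", "simulate_true_effects"]


def _as_corr(param: float | np.ndarray, k: int, name: str) -> np.ndarray:
    """Expand a scalar correlation into an equicorrelation matrix; validate PSD."""
    if np.isscalar(param):
        r = float(param)
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"{name} must lie in [-1, 1], got {r}")
        mat = np.full((k, k), r)
        np.fill_diagonal(mat, 1.0)
    else:
        mat = np.asarray(param, dtype=float)
        if mat.shape != (k, k):
            raise ValueError(f"{name} must be {k}x{k}, got {mat.shape}")
    if np.linalg.eigvalsh(mat).min() < -1e-10:
        raise ValueError(f"{name} correlation matrix is not positive semidefinite")
    return mat


@dataclass
class TrueEffectSet:
    """Per-(ancestry, trait) standardized-scale effect vectors plus ground truth."""

    variant_ids: np.ndarray
    causal: np.ndarray  # boolean mask, length M
    effects: dict[tuple[str, str], np.ndarray]  # (ancestry, trait) -> length-M vector
    h2: dict[str, float]  # per trait
    p_causal: float
    rg_anc: np.ndarray
    rg_trait: np.ndarray
    ancestries: list[str] = field(default_factory=list)
    traits: list[str] = field(default_factory=list)

    def effect_vector(self, ancestry: str, trait: str) -> np.ndarray:
        return self.effects[(ancestry, trait)]


def simulate_true_effects(
    panel_set: dict[str, LDPanel],
    p_causal: float,
    h2: float | dict[str, float],
    rg_anc: float | np.ndarray,
    rg_trait: float | np.ndarray,
    seed: int,
    traits: list[str] | None = None,
) -> TrueEffectSet:
    """Draw a shared causal architecture over a set of aligned panels.

    ``h2`` may be a scalar (all traits) or a per-trait dict.  After the
    correlated draw, each (ancestry, trait) vector ``b`` is rescaled so
    that ``sum_blocks b' R b`` equals the trait's h2 under that
    ancestry's panel (rescaling leaves cross correlations untouched).
    """
    if not 0.0 < p_causal <= 1.0:
        raise ValueError(f"p_causal must lie in (0, 1], got {p_causal}")
    ancestries = list(panel_set.keys())
    traits = list(traits) if traits is not None else ["trait"]
    a_n, t_n = len(ancestries), len(traits)
    h2_map = {t: float(h2) for t in traits} if np.isscalar(h2) else {t: float(h2[t]) for t in traits}
    for t, v in h2_map.items():
        if not 0.0 <= v < 1.0:
            raise ValueError(f"h2 for {t} must lie in [0, 1), got {v}")

    ref = panel_set[ancestries[0]]
    ids = ref.variant_ids
    M = len(ids)
    for a in ancestries[1:]:
        if not np.array_equal(panel_set[a].variant_ids, ids):
            raise ValueError("panels in a set must share identical variant ids in order")

    sig_a = _as_corr(rg_anc, a_n, "rg_anc")
    sig_t = _as_corr(rg_trait, t_n, "rg_trait")

    rng = substream(seed, "true-effects")
    causal = rng.random(M) < p_causal
    if p_causal == 1.0:
        causal[:] = True
    if not causal.any():
        causal[int(rng.integers(M))] = True
    n_causal = int(causal.sum())

    # joint draw: rows = causal variants, cols = (ancestry, trait) pairs
    kron = np.kron(sig_a, sig_t)
    w, v = np.linalg.eigh(kron)
    chol_like = v * np.sqrt(np.clip(w, 0.0, None))
    raw = rng.standard_normal((n_causal, a_n * t_n)) @ chol_like.T

    effects: dict[tuple[str, str], np.ndarray] = {}
    for ai, a in enumerate(ancestries):
        slices = panel_set[a].block_slices()
        for ti, t in enumerate(traits):
            b = np.zeros(M)
            b[causal] = raw[:, ai * t_n + ti]
            target = h2_map[t]
            if target == 0.0:
                b[:] = 0.0
            else:
                gvar = sum(b[s] @ panel_set[a].blocks[i].corr @ b[s] for i, s in enumerate(slices))
                if gvar <= 0:
                    raise ValueError("degenerate effect draw with zero genetic variance")
                b *= np.sqrt(target / gvar)
            effects[(a, t)] = b

    return TrueEffectSet(
        variant_ids=ids,
        causal=causal,
        effects=effects,
        h2=h2_map,
        p_causal=float(p_causal),
        rg_anc=sig_a,
        rg_trait=sig_t,
        ancestries=ancestries,
        traits=traits,
    )
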