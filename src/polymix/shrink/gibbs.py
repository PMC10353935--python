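"""Spike-and-slab posterior-mean effect sizes under block LD.

Single-site Gibbs over standardized effects.  Each variant is causal
with prior probability p, with slab variance h2_prior / (M * p).  The
conditional update residualizes the marginal effect against the current
values of the variant's LD partners within its block; the returned
weight is the Rao-Blackwellized across-iteration mean of the conditional
posterior mean (post burn-in), mapped back to the per-allele scale.
Blocks are processed independently; the whole pass is deterministic
given a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from polymix._rng import subseed
from polymix.shrink.weights import WeightSet
from polymix.simcohort.gwas import SummaryStats
from polymix.simcohort.ldpanel import LDPanel

__all__ = ["GibbsConfig", "posterior_mean_effects", "sparsify_block"]

logger = logging.getLogger(__name__)

FREQ_BOUNDS = (0.005, 0.995)
SPARSE_R_CUTOFF = 0.01
PSD_EIG_FLOOR = 1e-8


@dataclass
class GibbsConfig:
    iterations: int = 500  # kept iterations
    burn_in: int = 500
    seed: int = 0


@njit(cache=True)
def _gibbs_block(r_mat, bhat, n_eff, p, sigma2, n_burn, n_keep, seed, trace_out):
    """Gibbs over one LD block; returns Rao-Blackwellized posterior means.

    trace_out: optional (n_keep,) array filled with the per-iteration mean
    of conditional posterior means for MC-error diagnostics (pass length-0
    array to skip).
    """
    np.random.seed(seed)
    m = bhat.shape[0]
    beta = np.zeros(m)
    acc = np.zeros(m)
    log_prior_odds = np.log(p / (1.0 - p)) if p < 1.0 else 0.0
    want_trace = trace_out.shape[0] == n_keep
    for it in range(n_burn + n_keep):
        it_mean = 0.0
        for j in range(m):
            dot = 0.0
            for k in range(m):
                dot += r_mat[j, k] * beta[k]
            resid = bhat[j] - (dot - r_mat[j, j] * beta[j])
            nj = n_eff[j]
            v_slab = sigma2 + 1.0 / nj
            if p >= 1.0:
                ppost = 1.0
            else:
                # log density ratio slab / spike at the residualized effect
                d = (
                    -0.5 * np.log(v_slab)
                    - 0.5 * resid * resid / v_slab
                    + 0.5 * np.log(1.0 / nj)
                    + 0.5 * resid * resid * nj
                )
                lo = log_prior_odds + d
                if lo > 35.0:
                    ppost = 1.0
                elif lo < -35.0:
                    ppost = 0.0
                else:
                    ppost = 1.0 / (1.0 + np.exp(-lo))
            shrink = sigma2 / (sigma2 + 1.0 / nj)
            mu = shrink * resid
            if np.random.random() < ppost:
                beta[j] = mu + np.sqrt(shrink / nj) * np.random.randn()
            else:
                beta[j] = 0.0
            if it >= n_burn:
                cond_mean = ppost * mu
                acc[j] += cond_mean
                it_mean += cond_mean
        if want_trace and it >= n_burn:
            trace_out[it - n_burn] = it_mean / m
    return acc / n_keep


def sparsify_block(corr: np.ndarray, cutoff: float = SPARSE_R_CUTOFF) -> np.ndarray:
    """Zero small off-diagonal correlations, then repair PSD by eigenvalue clipping."""
    out = corr.copy()
    off = np.abs(out) < cutoff
    np.fill_diagonal(off, False)
    out[off] = 0.0
    w = np.linalg.eigvalsh(out)
    if w.min() < PSD_EIG_FLOOR:
        w, v = np.linalg.eigh(out)
        out = (v * np.clip(w, PSD_EIG_FLOOR, None)) @ v.T
        logger.info("sparsified LD block required PSD repair (min eig %.3g)", w.min())
    return out


def _effective_n(tab: pd.DataFrame) -> np.ndarray:
    n = tab["n"].to_numpy(dtype=float)
    if "n_cases" in tab.columns and tab["n_cases"].notna().all():
        cases = tab["n_cases"].to_numpy(dtype=float)
        controls = n - cases
        with np.errstate(divide="ignore"):
            n_eff = 4.0 / (1.0 / cases + 1.0 / controls)
        bad = (cases <= 0) | (controls <= 0)
        n_eff[bad] = n[bad]
        return n_eff
    return n


def posterior_mean_effects(
    sumstats: SummaryStats,
    panel: LDPanel,
    p: float,
    h2_prior: float,
    sparse: bool = False,
    gibbs_config: GibbsConfig | None = None,
) -> WeightSet:
    """Posterior-mean per-allele weights for one hyperparameter setting."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must lie in (0, 1], got {p}")
    if h2_prior <= 0:
        raise ValueError(f"h2_prior must be > 0, got {h2_prior}")
    cfg = gibbs_config or GibbsConfig()

    ptab = panel.variant_table().rename(columns={"freq": "panel_freq"})
    tab = sumstats.table.merge(
        ptab[["variant_id", "panel_freq", "block"]], on="variant_id", how="inner"
    )
    n_dropped = len(sumstats.table) - len(tab)
    if n_dropped:
        logger.info("dropped %d summary-stat variants absent from the panel", n_dropped)
    usable = (
        tab["beta"].notna()
        & tab["se"].notna()
        & (tab["panel_freq"] >= FREQ_BOUNDS[0])
        & (tab["panel_freq"] <= FREQ_BOUNDS[1])
    )
    tab = tab[usable]
    if len(tab) == 0:
        raise ValueError("no usable variants after matching sumstats to panel")

    m_total = len(tab)
    sigma2 = h2_prior / (m_total * p)
    freq = tab["panel_freq"].to_numpy()
    scale = np.sqrt(2.0 * freq * (1.0 - freq))  # per-allele -> standardized
    bhat_std = tab["beta"].to_numpy() * scale
    n_eff = _effective_n(tab)

    post_std = np.zeros(m_total)
    block_ids = tab["block"].to_numpy()
    id_to_block = {i: b for i, b in enumerate(panel.blocks)}
    pos = {bid: np.flatnonzero(block_ids == bid) for bid in np.unique(block_ids)}
    empty = np.empty(0)
    for bid, idx in pos.items():
        block = id_to_block[int(bid)]
        vid_order = {v: i for i, v in enumerate(block.variants["variant_id"])}
        sel = np.array([vid_order[v] for v in tab["variant_id"].to_numpy()[idx]])
        r_sub = block.corr[np.ix_(sel, sel)]
        if sparse:
            r_sub = sparsify_block(r_sub)
        post_std[idx] = _gibbs_block(
            np.ascontiguousarray(r_sub),
            np.ascontiguousarray(bhat_std[idx]),
            np.ascontiguousarray(n_eff[idx]),
            float(p),
            float(sigma2),
            int(cfg.burn_in),
            int(cfg.iterations),
            subseed(cfg.seed, "gibbs", int(bid)),
            empty,
        )

    table = pd.DataFrame(
        {
            "rsID": tab["variant_id"].to_numpy(),
            "chr_name": tab["chr"].to_numpy(),
            "chr_position": tab["pos"].to_numpy(),
            "effect_allele": tab["effect_allele"].to_numpy(),
            "other_allele": tab["other_allele"].to_numpy(),
            "effect_weight": post_std / scale,
        }
    )
    ws = WeightSet(
        table=table,
        metadata={
            "trait": sumstats.trait,
            "ancestry": sumstats.ancestry,
            "p": float(p),
            "h2_prior": float(h2_prior),
            "sparse": bool(sparse),
            "iterations": cfg.iterations,
            "burn_in": cfg.burn_in,
        },
    )
    ws.validate()
    return ws
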