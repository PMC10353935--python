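"""Block-diagonal LD reference panels.

A panel is an ordered list of independent blocks; within a block the
variant-variant correlation follows a first-order autoregressive decay,
optionally perturbed per ancestry so that several panels share variants
but differ in LD and allele frequency (a free "divergence" knob, not a
fit to any real population pair).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from polymix._rng import substream

__all__ = [
    "LDBlock",
    "LDPanel",
    "simulate_ld_panel",
    "simulate_panel_set",
    "write_ld_panel",
    "read_ld_panel",
]

# non-ambiguous allele pairs only, so simulated variants survive strand checks
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class LDBlock:
    """One LD block: variant metadata plus a dense correlation matrix."""

    variants: pd.DataFrame  # columns: variant_id, chrom, pos, effect_allele, other_allele, freq
    corr: np.ndarray

    @property
    def size(self) -> int:
        return len(self.variants)

    def validate(self) -> None:
        m = self.size
        if self.corr.shape != (m, m):
            raise ValueError(f"correlation matrix shape {self.corr.shape} != ({m}, {m})")
        if not np.allclose(self.corr, self.corr.T, atol=1e-12):
            raise ValueError("correlation matrix not symmetric")
        if not np.allclose(np.diag(self.corr), 1.0, atol=1e-12):
            raise ValueError("correlation matrix diagonal not 1")
        w = np.linalg.eigvalsh(self.corr)
        if w.min() < -1e-8:
            raise ValueError(f"correlation matrix has eigenvalue {w.min():.3g} < -1e-8")
        f = self.variants["freq"].to_numpy()
        if np.any(f <= 0.0) or np.any(f >= 1.0):
            raise ValueError("allele frequencies must lie strictly in (0, 1)")


@dataclass
class LDPanel:
    """Ancestry-labelled, block-diagonal variant correlation reference."""

    ancestry: str
    blocks: list[LDBlock] = field(default_factory=list)

    @property
    def n_variants(self) -> int:
        return sum(b.size for b in self.blocks)

    @property
    def variant_ids(self) -> np.ndarray:
        return np.concatenate([b.variants["variant_id"].to_numpy() for b in self.blocks])

    @property
    def freqs(self) -> np.ndarray:
        return np.concatenate([b.variants["freq"].to_numpy() for b in self.blocks])

    def variant_table(self) -> pd.DataFrame:
        """All variant metadata (with block index) in panel order."""
        parts = []
        for i, b in enumerate(self.blocks):
            t = b.variants.copy()
            t["block"] = i
            parts.append(t)
        return pd.concat(parts, ignore_index=True)

    def block_slices(self) -> list[slice]:
        out, start = [], 0
        for b in self.blocks:
            out.append(slice(start, start + b.size))
            start += b.size
        return out

    def validate(self) -> None:
        for b in self.blocks:
            b.validate()
        ids = self.variant_ids
        if len(np.unique(ids)) != len(ids):
            raise ValueError("variant ids are not unique across blocks")

    def ld_scores(self) -> np.ndarray:
        """Per-variant sum of squared within-block correlations (incl. self)."""
        return np.concatenate([(b.corr**2).sum(axis=1) for b in self.blocks])


def _ar1(m: int, rho: float) -> np.ndarray:
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_ld_panel(
    n_blocks: int,
    block_size_range: tuple[int, int],
    decay_param: float,
    ancestry_divergence: float,
    seed: int,
    ancestry_label: str = "ANC",
) -> LDPanel:
    """Simulate a block-diagonal AR(1) LD panel for one ancestry.

    The base structure (block sizes, variant metadata, base frequencies and
    base AR(1) decay per block) depends only on ``(n_blocks,
    block_size_range, decay_param, seed)``.  The ancestry perturbation
    (allele-frequency drift and LD jitter, both scaled by
    ``ancestry_divergence``) depends on ``(seed, ancestry_label)``, so
    panels generated for several labels from one seed share variants and a
    common backbone.  Adjacent-variant base correlation is
    ``exp(-decay_param)``; entry (i, j) of a block is that value raised to
    ``|i - j|`` when divergence is 0.

    Parameters
    ----------
    ancestry_divergence : float in [0, 1]
        0 reproduces the shared backbone exactly.
    """
    lo, hi = int(block_size_range[0]), int(block_size_range[1])
    if lo < 1 or hi < lo:
        raise ValueError(f"block sizes must be >= 1 and ordered, got {block_size_range}")
    if decay_param <= 0:
        raise ValueError("decay_param must be > 0")
    if not 0.0 <= ancestry_divergence <= 1.0:
        raise ValueError("ancestry_divergence must lie in [0, 1]")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")

    base = substream(seed, "ldpanel-base")
    anc = substream(seed, "ldpanel-anc", ancestry_label)
    rho_base = float(np.exp(-decay_param))
    d = float(ancestry_divergence)

    blocks: list[LDBlock] = []
    vidx = 0
    for bi in range(n_blocks):
        m = int(base.integers(lo, hi + 1))
        # frequencies cluster around a per-block base so high LD targets stay
        # attainable for thresholded genotypes (r is bounded by freq mismatch)
        fb = float(base.uniform(0.2, 0.8))
        f0 = np.clip(fb + base.normal(0.0, 0.005, size=m), 0.05, 0.95)
        pair_idx = base.integers(0, len(_ALLELE_PAIRS), size=m)
        rho_b = rho_base

        # ancestry streams are always consumed so panels stay aligned across labels
        fb_drift = float(anc.beta(max(fb * (1.0 - d) / max(d, 1e-9), 1e-3),
                                  max((1.0 - fb) * (1.0 - d) / max(d, 1e-9), 1e-3))) if d > 0 else fb
        jitter = anc.normal(0.0, 1.0, size=m)
        rho_jit = float(anc.normal(0.0, 1.0))
        if d > 0:
            # block-level Balding-Nichols drift plus small per-variant jitter
            f = np.clip(f0 + (fb_drift - fb) + 0.002 * d * jitter, 0.05, 0.95)
            rho = float(np.clip(rho_b + 0.1 * d * rho_jit, 0.0, 0.95))
        else:
            f = f0
            rho = rho_b

        corr = _ar1(m, rho)
        variants = pd.DataFrame(
            {
                "variant_id": [f"rs{vidx + j}" for j in range(m)],
                "chrom": (bi % 22) + 1,
                "pos": [1000 * (bi + 1) + j for j in range(m)],
                "effect_allele": [_ALLELE_PAIRS[k][0] for k in pair_idx],
                "other_allele": [_ALLELE_PAIRS[k][1] for k in pair_idx],
                "freq": f,
            }
        )
        blocks.append(LDBlock(variants=variants, corr=corr))
        vidx += m

    panel = LDPanel(ancestry=ancestry_label, blocks=blocks)
    panel.validate()
    return panel


def simulate_panel_set(
    ancestries: list[str],
    n_blocks: int,
    block_size_range: tuple[int, int],
    decay_param: float,
    ancestry_divergence: float,
    seed: int,
) -> dict[str, LDPanel]:
    """One panel per ancestry label, sharing variants and backbone structure."""
    return {
        a: simulate_ld_panel(
            n_blocks, block_size_range, decay_param, ancestry_divergence, seed, ancestry_label=a
        )
        for a in ancestries
    }


def write_ld_panel(panel: LDPanel, directory: str | Path) -> Path:
    """Persist a panel as one directory: a manifest plus per-block TSV files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"ancestry": panel.ancestry, "n_blocks": len(panel.blocks), "blocks": []}
    for i, b in enumerate(panel.blocks):
        vfile = f"block{i:04d}.variants.tsv"
        cfile = f"block{i:04d}.corr.tsv"
        b.variants.to_csv(directory / vfile, sep="\t", index=False, float_format="%.17g")
        np.savetxt(directory / cfile, b.corr, delimiter="\t", fmt="%.17g")
        manifest["blocks"].append({"variants": vfile, "corr": cfile, "size": b.size})
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return directory


def read_ld_panel(directory: str | Path) -> LDPanel:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    blocks = []
    for entry in manifest["blocks"]:
        variants = pd.read_csv(directory / entry["variants"], sep="\t")
        corr = np.loadtxt(directory / entry["corr"], delimiter="\t", ndmin=2)
        blocks.append(LDBlock(variants=variants, corr=corr))
    panel = LDPanel(ancestry=manifest["ancestry"], blocks=blocks)
    panel.validate()
    return panel
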