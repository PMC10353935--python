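"""Genotype dosage simulation from an LD panel.

Each variant's two alleles come from thresholding two independent latent
multivariate-Gaussian haplotype draws at the frequency-derived cutpoint,
so the dosage is in {0, 1, 2} with mean 2f under Hardy-Weinberg.  The
panel correlation is the *realized* (post-threshold) target: the latent
correlation is calibrated pairwise through the bivariate-normal relation

    cov(I(Z1 > t1), I(Z2 > t2)) = integral_0^rho phi2(t1, t2; r) dr

(Sheppard/Plackett identity), inverted on a dense grid.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from polymix._rng import substream
from polymix.simcohort.ldpanel import LDPanel

__all__ = ["simulate_genotypes", "latent_correlation"]

_RHO_GRID = np.linspace(-0.999, 0.999, 1201)
_CALIBRATION_CACHE: dict[tuple[bytes, bytes], np.ndarray] = {}


def _binary_cov_grid(t1: float, t2: float) -> np.ndarray:
    """cov(I(Z1>t1), I(Z2>t2)) as a function of latent rho, on _RHO_GRID."""
    r = _RHO_GRID
    om = 1.0 - r * r
    dens = np.exp(-(t1 * t1 - 2.0 * r * t1 * t2 + t2 * t2) / (2.0 * om)) / (2.0 * np.pi * np.sqrt(om))
    # cumulative integral from rho=0 outward
    cum = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2.0 * np.diff(r))])
    i0 = np.searchsorted(r, 0.0)
    return cum - np.interp(0.0, r, cum)


def latent_correlation(r_target: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Calibrate the latent Gaussian correlation matrix for one block.

    Parameters
    ----------
    r_target : (m, m) realized genotype correlation target.
    freqs : (m,) allele frequencies.

    Returns a PSD-repaired latent correlation matrix.
    """
    key = (r_target.tobytes(), freqs.tobytes())
    cached = _CALIBRATION_CACHE.get(key)
    if cached is not None:
        return cached
    m = len(freqs)
    t = norm.ppf(1.0 - freqs)  # allele present when Z > t
    sd = np.sqrt(freqs * (1.0 - freqs))
    latent = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            rt = r_target[i, j]
            if abs(rt) < 1e-4:
                continue
            cov_curve = _binary_cov_grid(t[i], t[j])
            target_cov = rt * sd[i] * sd[j]
            target_cov = float(np.clip(target_cov, cov_curve[0], cov_curve[-1]))
            rl = float(np.interp(target_cov, cov_curve, _RHO_GRID))
            latent[i, j] = latent[j, i] = np.clip(rl, -0.999, 0.999)
    # PSD repair: clip eigenvalues, restore unit diagonal
    w, v = np.linalg.eigh(latent)
    if w.min() < 1e-8:
        w = np.clip(w, 1e-8, None)
        latent = (v * w) @ v.T
        dscale = np.sqrt(np.diag(latent))
        latent = latent / np.outer(dscale, dscale)
    _CALIBRATION_CACHE[key] = latent
    return latent


def simulate_genotypes(panel: LDPanel, n: int, seed: int) -> np.ndarray:
    """Draw an ``n x M`` dosage matrix ({0,1,2} floats) from ``panel``.

    Per-variant mean is ~``2 * freq``; within-block genotype correlation
    matches the panel correlation (blocks independent).  Deterministic
    given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = substream(seed, "genotypes", panel.ancestry)
    out = np.empty((n, panel.n_variants), dtype=np.float64)
    col = 0
    for block in panel.blocks:
        m = block.size
        f = block.variants["freq"].to_numpy()
        t = norm.ppf(1.0 - f)
        latent = latent_correlation(block.corr, f)
        chol = np.linalg.cholesky(latent)
        # two latent haplotype draws per individual
        z1 = rng.standard_normal((n, m)) @ chol.T
        z2 = rng.standard_normal((n, m)) @ chol.T
        out[:, col : col + m] = (z1 > t).astype(np.float64) + (z2 > t).astype(np.float64)
        col += m
    return out
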