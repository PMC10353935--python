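"""Shared fixtures: small panels, effects and cohorts built once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from polymix.simcohort import (
    LDBlock,
    LDPanel,
    simulate_cohort,
    simulate_panel_set,
    simulate_true_effects,
)


def make_panel(freqs, corr, ancestry="TEST", start_id=0) -> LDPanel:
    """Single-block panel from explicit frequencies and correlation matrix."""
    m = len(freqs)
    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{start_id + i}" for i in range(m)],
            "chrom": 1,
            "pos": np.arange(m) + 1,
            "effect_allele": "A",
            "other_allele": "G",
            "freq": np.asarray(freqs, dtype=float),
        }
    )
    panel = LDPanel(ancestry=ancestry, blocks=[LDBlock(variants=variants, corr=np.asarray(corr, dtype=float))])
    panel.validate()
    return panel


def identity_panel(m: int, freq: float = 0.5, ancestry="TEST") -> LDPanel:
    return make_panel(np.full(m, freq), np.eye(m), ancestry=ancestry)


def sumstats_from_arrays(panel, beta, se, n, n_cases=np.nan, trait="t", ancestry="TEST"):
    """SummaryStats aligned to a panel, with p recomputed from beta/se."""
    from scipy.stats import norm

    from polymix.simcohort.gwas import SummaryStats

    vt = panel.variant_table()
    beta = np.asarray(beta, dtype=float)
    se = np.broadcast_to(np.asarray(se, dtype=float), beta.shape)
    tab = pd.DataFrame(
        {
            "variant_id": vt["variant_id"],
            "chr": vt["chrom"],
            "pos": vt["pos"],
            "effect_allele": vt["effect_allele"],
            "other_allele": vt["other_allele"],
            "eaf": vt["freq"],
            "beta": beta,
            "se": se,
            "p": 2 * norm.sf(np.abs(beta / se)),
            "n": n,
            "n_cases": n_cases,
        }
    )
    ss = SummaryStats(tab, trait=trait, ancestry=ancestry)
    ss.validate()
    return ss


@pytest.fixture(scope="session")
def panel_trio():
    """Three divergent ancestry panels sharing ~120 variants."""
    return simulate_panel_set(["EUR", "AFR", "SAS"], 10, (8, 16), 0.2, 0.2, seed=11)


@pytest.fixture(scope="session")
def effects_trio(panel_trio):
    return simulate_true_effects(
        panel_trio, 0.2, {"cad": 0.5, "lipid": 0.4}, 0.9, 0.7, seed=12, traits=["cad", "lipid"]
    )


@pytest.fixture(scope="session")
def cohort_eur(panel_trio, effects_trio):
    """Single-ancestry cohort: flattening is affine-exact within one group."""
    return simulate_cohort(
        panel_trio,
        effects_trio,
        {"EUR": 2500},
        prevalence_K=0.15,
        incident_rate=0.01,
        followup_years=12.0,
        seed=14,
        clinical_model={"intercept": -3.0, "age": 0.05, "sex": 0.5, "traits": {"lipid": 0.3}},
    )


@pytest.fixture(scope="session")
def cohort_trio(panel_trio, effects_trio):
    return simulate_cohort(
        panel_trio,
        effects_trio,
        {"EUR": 1500, "AFR": 800, "SAS": 800},
        prevalence_K=0.15,
        incident_rate=0.01,
        followup_years=12.0,
        seed=13,
        clinical_model={"intercept": -3.0, "age": 0.05, "sex": 0.5, "traits": {"lipid": 0.3}},
    )
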