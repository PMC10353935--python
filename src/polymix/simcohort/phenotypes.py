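"""Cohort assembly: liability-threshold disease, incident events, covariates.

Disease liability is the standardized genetic score plus normal noise of
variance 1 - h2; prevalent cases are liabilities above the (1 - K)
normal quantile.  Incident event times are exponential with a log-hazard
linear in the standardized genetic score (plus an optional extra hazard
for prevalent cases, used by risk-equivalence analyses); administrative
censoring applies at the follow-up horizon.  The clinical 10-year risk
column is a plain logistic function of age, sex and simulated
quantitative risk-factor traits, standing in for an external estimator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.linalg import svds
from scipy.stats import norm

from polymix._rng import substream
from polymix.simcohort.effects import TrueEffectSet
from polymix.simcohort.genotypes import simulate_genotypes
from polymix.simcohort.ldpanel import LDPanel

__all__ = ["Cohort", "simulate_phenotypes", "simulate_cohort", "write_cohort", "read_cohort"]

N_PCS = 10

DEFAULT_CLINICAL_MODEL = {"intercept": -3.0, "age": 0.05, "sex": 0.5, "traits": {}}


@dataclass
class Cohort:
    """Dosage matrix plus per-sample phenotype/covariate table."""

    data: pd.DataFrame
    dosages: np.ndarray
    variants: pd.DataFrame  # variant_id, chrom, pos, effect_allele, other_allele, freq

    @property
    def n(self) -> int:
        return len(self.data)

    def covariate_matrix(self) -> pd.DataFrame:
        """Baseline model covariates: age, sex, array dummies, PC1..PC10."""
        cols = {"age": self.data["age"], "sex": self.data["sex"]}
        arrays = sorted(self.data["array"].unique())
        for a in arrays[1:]:
            cols[f"array_{a}"] = (self.data["array"] == a).astype(float)
        for i in range(1, N_PCS + 1):
            cols[f"PC{i}"] = self.data[f"PC{i}"]
        return pd.DataFrame(cols, index=self.data.index)

    def pc_matrix(self) -> np.ndarray:
        return self.data[[f"PC{i}" for i in range(1, N_PCS + 1)]].to_numpy()

    def validate(self) -> None:
        if np.any((self.data["prevalent_case"] == 1) & (self.data["incident_case"] == 1)):
            # incident analyses must exclude prevalent cases; both may be coded
            # but incident_case is forced 0 for prevalent samples at build time
            raise ValueError("prevalent samples must have incident_case = 0")
        if np.any(self.data["follow_up_time"] <= 0):
            raise ValueError("follow_up_time must be positive")
        cr = self.data["clinical_risk_10yr"]
        if np.any((cr < 0) | (cr > 1)):
            raise ValueError("clinical_risk_10yr must lie in [0, 1]")


def _principal_components(dosages: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    # loadings from a row subsample, then one projection matmul; avoids
    # materializing the full standardized matrix (slow-allocation hosts)
    n, m = dosages.shape
    mu = dosages.mean(axis=0)
    sd = np.sqrt(np.maximum(np.einsum("ij,ij->j", dosages, dosages) / n - mu * mu, 0.0))
    sd[sd <= 0] = 1.0
    inv = 1.0 / sd

    n_fit = min(n, 4000)
    rows = np.sort(rng.choice(n, size=n_fit, replace=False)) if n > n_fit else np.arange(n)
    xs = (dosages[rows] - mu) * inv
    k = min(N_PCS, min(xs.shape) - 1)
    v0 = rng.standard_normal(min(xs.shape))
    _, s, vt = svds(xs, k=k, v0=v0)
    order = np.argsort(s)[::-1]
    loadings = vt[order].T  # (m, k)
    pcs = dosages @ (inv[:, None] * loadings) - (mu * inv) @ loadings
    # deterministic sign: largest-magnitude loading positive
    for j in range(pcs.shape[1]):
        i = np.argmax(np.abs(pcs[:, j]))
        if pcs[i, j] < 0:
            pcs[:, j] = -pcs[:, j]
    pcs = (pcs - pcs.mean(axis=0)) / pcs.std(axis=0)
    if k < N_PCS:  # pad tiny fixtures
        pcs = np.hstack([pcs, np.zeros((pcs.shape[0], N_PCS - k))])
    return pcs


def simulate_phenotypes(
    cohort_genotypes: dict[str, np.ndarray],
    panel_set: dict[str, LDPanel],
    effects: TrueEffectSet,
    prevalence_K: float,
    incident_rate: float,
    followup_years: float,
    seed: int,
    disease_trait: str | None = None,
    incident_log_hr_per_sd: float = 0.5,
    comorbidity_log_hr: float = 1.0,
    clinical_model: dict | None = None,
    compute_pcs: bool = True,
) -> Cohort:
    """Build a full Cohort from per-ancestry dosage matrices.

    ``cohort_genotypes`` maps ancestry label -> (n_a x M) dosage matrix,
    aligned to the panels' variant order.  The first trait in ``effects``
    is the disease trait unless ``disease_trait`` is given; remaining
    traits become quantitative risk-factor columns.
    """
    if not 0.0 < prevalence_K < 1.0:
        raise ValueError(f"prevalence_K must lie in (0, 1), got {prevalence_K}")
    if incident_rate <= 0:
        raise ValueError("incident_rate must be > 0")
    if followup_years <= 0:
        raise ValueError("followup_years must be > 0")
    for t, v in effects.h2.items():
        if v >= 1.0:
            raise ValueError(f"h2 for trait {t} must be < 1")
    disease_trait = disease_trait or effects.traits[0]
    clinical_model = clinical_model or DEFAULT_CLINICAL_MODEL
    rng = substream(seed, "phenotypes")
    h2 = effects.h2[disease_trait]
    thresh = norm.ppf(1.0 - prevalence_K)

    frames = []
    dosage_parts = []
    offset = 0
    for anc, dos in cohort_genotypes.items():
        panel = panel_set[anc]
        n_a = dos.shape[0]
        f = panel.freqs

        def x_std_dot(b: np.ndarray) -> np.ndarray:
            # (dos - 2f)/sqrt(2f(1-f)) @ b without the full-size temporary
            w = b / np.sqrt(2.0 * f * (1.0 - f))
            return dos @ w - (2.0 * f) @ w

        g = x_std_dot(effects.effect_vector(anc, disease_trait))
        liab = g + rng.normal(0.0, np.sqrt(max(1.0 - h2, 0.0)), size=n_a)
        prevalent = (liab > thresh).astype(int)
        z_g = g / np.sqrt(h2) if h2 > 0 else np.zeros(n_a)

        loghaz = np.log(incident_rate) + incident_log_hr_per_sd * z_g + comorbidity_log_hr * prevalent
        t_event = rng.exponential(1.0, size=n_a) / np.exp(loghaz)
        follow = np.minimum(np.maximum(t_event, 1e-6), followup_years)
        event = (t_event < followup_years).astype(int)
        incident = np.where(prevalent == 1, 0, event)

        row = {
            "sample_id": [f"{anc}_{offset + i}" for i in range(n_a)],
            "ancestry": anc,
            "age": np.round(rng.uniform(40.0, 70.0, size=n_a), 1),
            "sex": rng.integers(0, 2, size=n_a),
            "array": rng.choice(["axiom_a", "axiom_b"], size=n_a),
            "prevalent_case": prevalent,
            "incident_case": incident,
            "event_any": event,  # includes events among prevalent samples
            "follow_up_time": follow,
            "_true_genetic_score": z_g,
            "_liability": liab,
        }
        for t in effects.traits:
            if t == disease_trait:
                continue
            gt = x_std_dot(effects.effect_vector(anc, t))
            h2t = effects.h2[t]
            row[t] = gt + rng.normal(0.0, np.sqrt(max(1.0 - h2t, 0.0)), size=n_a)
        frames.append(pd.DataFrame(row))
        dosage_parts.append(dos)
        offset += n_a

    data = pd.concat(frames, ignore_index=True)
    dosages = dosage_parts[0] if len(dosage_parts) == 1 else np.vstack(dosage_parts)

    if compute_pcs:
        pcs = _principal_components(dosages, substream(seed, "pcs"))
    else:  # covariate-free GWAS cohorts can skip the SVD
        pcs = np.zeros((len(data), N_PCS))
    for i in range(N_PCS):
        data[f"PC{i + 1}"] = pcs[:, i]

    lin = (
        clinical_model["intercept"]
        + clinical_model["age"] * (data["age"].to_numpy() - 55.0)
        + clinical_model["sex"] * data["sex"].to_numpy()
    )
    for t, coef in clinical_model.get("traits", {}).items():
        lin = lin + coef * data[t].to_numpy()
    data["clinical_risk_10yr"] = 1.0 / (1.0 + np.exp(-lin))

    ref = panel_set[list(cohort_genotypes)[0]]
    variants = ref.variant_table()[["variant_id", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    variants["freq"] = dosages.mean(axis=0) / 2.0

    cohort = Cohort(data=data, dosages=dosages, variants=variants)
    cohort.validate()
    return cohort


def simulate_cohort(
    panel_set: dict[str, LDPanel],
    effects: TrueEffectSet,
    n_per_ancestry: dict[str, int] | int,
    prevalence_K: float,
    incident_rate: float,
    followup_years: float,
    seed: int,
    **kwargs,
) -> Cohort:
    """Convenience wrapper: simulate genotypes per ancestry, then phenotypes."""
    if isinstance(n_per_ancestry, int):
        n_per_ancestry = {a: n_per_ancestry for a in panel_set}
    genos = {
        a: simulate_genotypes(panel_set[a], n, seed=substream(seed, "geno", a).integers(2**31))
        for a, n in n_per_ancestry.items()
        if n > 0
    }
    return simulate_phenotypes(
        genos, panel_set, effects, prevalence_K, incident_rate, followup_years, seed=seed, **kwargs
    )


def write_cohort(cohort: Cohort, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort.data.to_csv(directory / "phenotypes.tsv", sep="\t", index=False, float_format="%.10g")
    cohort.variants.to_csv(directory / "variants.tsv", sep="\t", index=False, float_format="%.10g")
    np.savetxt(directory / "dosages.tsv", cohort.dosages, delimiter="\t", fmt="%g")
    (directory / "manifest.json").write_text(
        json.dumps({"n": cohort.n, "m": cohort.dosages.shape[1]}, indent=1)
    )
    return directory


def read_cohort(directory: str | Path) -> Cohort:
    directory = Path(directory)
    data = pd.read_csv(directory / "phenotypes.tsv", sep="\t")
    variants = pd.read_csv(directory / "variants.tsv", sep="\t")
    dosages = np.loadtxt(directory / "dosages.tsv", delimiter="\t", ndmin=2)
    return Cohort(data=data, dosages=dosages, variants=variants)
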