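"""Desk-scale experiment harnesses used by the acceptance suite.

Each experiment recomputes its quantity from scratch through the public
pipeline API at a scale that runs in minutes on one CPU; replicate seeds
are fanned out from one experiment seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from polymix._rng import subseed, substream
from polymix.evalrisk import hazard_per_sd, integrated_risk_model, odds_per_sd
from polymix.evalrisk.variance import delta_nagelkerke_r2, liability_r2
from polymix.mix import fit_mixing_weights, flatten_weights, stepwise_aic_select, tune_best_candidate
from polymix.score import score_cohort
from polymix.score.scoring import ScoreVector, standardize_scores
from polymix.shrink import GridConfig, enumerate_grid, estimate_heritability_ldsc
from polymix.simcohort import (
    run_gwas,
    simulate_cohort,
    simulate_ld_panel,
    simulate_panel_set,
    simulate_true_effects,
)

__all__ = [
    "multi_ancestry_gain_experiment",
    "h2_recovery_experiment",
    "mixing_ratio_experiment",
    "null_calibration_experiment",
]


def _two_layer_replicate(seed: int, panels, prevalence: float = 0.15) -> dict:
    """One replicate: single-ancestry candidate vs flattened two-layer score."""
    effects = simulate_true_effects(
        panels, 0.15, {"cad": 0.5, "lipid": 0.5}, 0.95, 0.8,
        seed=subseed(seed, "eff"), traits=["cad", "lipid"],
    )
    common = dict(
        prevalence_K=prevalence, incident_rate=0.02, followup_years=12.0, incident_log_hr_per_sd=0.5
    )
    gwas_specs = {
        ("cad", "EUR"): 1000,  # deliberately under-powered target-ancestry GWAS
        ("cad", "AFR"): 12000,
        ("cad", "SAS"): 12000,
        ("lipid", "EUR"): 10000,
    }
    sizes: dict[str, int] = {}
    for (_, a), n in gwas_specs.items():
        sizes[a] = max(sizes.get(a, 0), n)
    gwas_cohorts = {
        a: simulate_cohort(
            {a: panels[a]}, effects, {a: n}, seed=subseed(seed, "gw", a), compute_pcs=False, **common
        )
        for a, n in sizes.items()
    }
    grid = GridConfig(
        causal_fractions=[0.1, 1.0], h2_scales=[1.0], sparse_flags=[False],
        gibbs_iterations=100, burn_in=100, seed=subseed(seed, "grid"),
    )
    candidates = {}
    for (t, a) in gwas_specs:
        outcome = "prevalent_case" if t == "cad" else t
        ss = run_gwas(gwas_cohorts[a], outcome, "auto")
        ss.trait, ss.ancestry = t, a
        candidates[(t, a)] = enumerate_grid(ss, panels[a], grid, h2_hat=0.5)

    train = simulate_cohort(panels, effects, {"EUR": 3000}, seed=subseed(seed, "train"), **common)
    valid = simulate_cohort(panels, effects, {"EUR": 8000}, seed=subseed(seed, "valid"), **common)
    covs = train.covariate_matrix()
    y = train.data["prevalent_case"].to_numpy()

    tuned = {k: tune_best_candidate(v, train)[0] for k, v in candidates.items()}

    sv_tr, consts, _ = score_cohort(train, tuned[("cad", "EUR")])
    sv_single, _, _ = score_cohort(valid, tuned[("cad", "EUR")], constants=consts)

    l1_models, l1_raw = {}, {}
    for t, ancs in (("cad", ["EUR", "AFR", "SAS"]), ("lipid", ["EUR"])):
        frames, cc = {}, {}
        for a in ancs:
            sv, c, _ = score_cohort(train, tuned[(t, a)], score_id=f"{t}|{a}")
            frames[a] = sv.standardized
            cc[a] = c
        frame = pd.DataFrame(frames)
        sel, trace = stepwise_aic_select(frame, y, covs)
        if not sel:
            sel = [frame.columns[0]]
        model = fit_mixing_weights(
            frame[sel], y, covs, constants=cc, layer=1, components=list(frame.columns), aic_trace=trace
        )
        l1_models[t] = model
        l1_raw[t] = model.combine(frame)

    l2_std, l2_c = {}, {}
    for t, raw in l1_raw.items():
        sv2, c2 = standardize_scores(
            ScoreVector(train.data["sample_id"].to_numpy(), raw, train.data["ancestry"].to_numpy()),
            train.pc_matrix(),
        )
        l2_std[t] = sv2.standardized
        l2_c[t] = c2
    frame2 = pd.DataFrame(l2_std)
    sel2, trace2 = stepwise_aic_select(frame2, y, covs)
    if "cad" not in sel2:
        sel2 = ["cad"] + sel2
    l2 = fit_mixing_weights(
        frame2[sel2], y, covs, constants=l2_c, layer=2, components=list(frame2.columns), aic_trace=trace2
    )
    flat = flatten_weights(l1_models, l2, tuned)
    _, fconsts, _ = score_cohort(train, flat)
    sv_multi, _, _ = score_cohort(valid, flat, constants=fconsts)

    out = {}
    for name, s in (("single", sv_single.standardized), ("multi", sv_multi.standardized)):
        d = delta_nagelkerke_r2(s, valid)
        out[f"{name}_liability_r2"] = liability_r2(d, prevalence, valid.data["prevalent_case"].mean())
        out[f"{name}_hr_per_sd"] = hazard_per_sd(s, valid).estimate
    return out


def multi_ancestry_gain_experiment(seed: int, n_reps: int = 10) -> pd.DataFrame:
    """Two-layer combined score vs best single-ancestry candidate, per replicate."""
    panels = simulate_panel_set(["EUR", "AFR", "SAS"], 12, (25, 35), 0.25, 0.15, seed=subseed(seed, "panels"))
    rows = [_two_layer_replicate(subseed(seed, "rep", r), panels) for r in range(n_reps)]
    df = pd.DataFrame(rows)
    df["win_r2"] = df["multi_liability_r2"] > df["single_liability_r2"]
    df["win_hr"] = df["multi_hr_per_sd"] > df["single_hr_per_sd"]
    return df


def h2_recovery_experiment(
    seed: int, n_seeds: int = 10, h2: float = 0.3, n: int = 20_000, n_blocks: int = 40
) -> list[float]:
    """LD-score-regression h2 estimates over seeded replicates (M ~ 2,000)."""
    panel = simulate_ld_panel(n_blocks, (40, 60), 0.25, 0.0, seed=subseed(seed, "panel"), ancestry_label="A")
    panels = {"A": panel}
    out = []
    for r in range(n_seeds):
        eff = simulate_true_effects(panels, 0.5, h2, 1.0, 1.0, seed=subseed(seed, "eff", r), traits=["y"])
        cohort = simulate_cohort(
            panels, eff, {"A": n}, prevalence_K=0.5, incident_rate=0.01, followup_years=5.0,
            seed=subseed(seed, "cohort", r), compute_pcs=False,
        )
        ss = run_gwas(cohort, "_liability", "linear")
        out.append(estimate_heritability_ldsc(ss, panel).h2_hat)
    return out


def mixing_ratio_experiment(seed: int, n: int = 50_000) -> float:
    """Fitted mixing-coefficient ratio for a 0.6/0.3 generating mixture."""
    rng = substream(seed, "mixing")
    s1, s2 = rng.standard_normal(n), rng.standard_normal(n)
    lin = -2.0 + 0.6 * s1 + 0.3 * s2
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-lin))).astype(int)
    model = fit_mixing_weights(pd.DataFrame({"s1": s1, "s2": s2}), y)
    return model.beta["s1"] / model.beta["s2"]


def null_calibration_experiment(seed: int, n_reps: int = 100, n: int = 2000) -> dict[str, float]:
    """95% CI coverage of null OR/SD, HR/SD and interaction terms."""
    cover = {"or": 0, "hr": 0, "interaction": 0}
    for r in range(n_reps):
        rng = substream(seed, "null", r)
        score = rng.standard_normal(n)
        age = rng.uniform(40, 70, n).round(1)
        sex = rng.integers(0, 2, n)
        clin = np.clip(rng.beta(2, 12, n), 0.001, 0.6)
        # outcome depends on covariates/clinical risk but never on the score
        p_prev = 1.0 / (1.0 + np.exp(-(-2.0 + 0.03 * (age - 55))))
        prev = (rng.random(n) < p_prev).astype(int)
        rate = 0.02 * np.exp(2.0 * clin)
        t = rng.exponential(1.0, n) / rate
        follow = np.minimum(t, 12.0)
        inc = np.where(prev == 1, 0, (t < 12.0).astype(int))
        data = pd.DataFrame(
            {
                "sample_id": np.arange(n),
                "ancestry": "A",
                "age": age,
                "sex": sex,
                "array": "axiom_a",
                "prevalent_case": prev,
                "incident_case": inc,
                "follow_up_time": follow,
                "clinical_risk_10yr": clin,
            }
        )
        for i in range(1, 11):
            data[f"PC{i}"] = rng.normal(size=n)
        covs = data[["age", "sex"]].astype(float)
        cohort = type(
            "C",
            (),
            {
                "data": data,
                "covariate_matrix": lambda self=None, d=data: d[["age", "sex"]].astype(float),
                "pc_matrix": lambda self=None, d=data: d[[f"PC{i}" for i in range(1, 11)]].to_numpy(),
            },
        )()
        o = odds_per_sd(score, cohort, covariates=covs)
        cover["or"] += o.ci_low <= 1.0 <= o.ci_high
        h = hazard_per_sd(score, cohort, covariates=covs)
        cover["hr"] += h.ci_low <= 1.0 <= h.ci_high
        m = integrated_risk_model(score, clin, cohort)
        lo, hi = m.interaction_ci
        cover["interaction"] += lo <= 0.0 <= hi
    return {k: v / n_reps for k, v in cover.items()}
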