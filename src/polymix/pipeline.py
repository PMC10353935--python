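"""Config-driven pipeline: simulate -> shrink -> score -> mix -> evaluate.

One global seed is fanned out to per-stage substreams through
``polymix._rng`` (stage name and labels enter the spawn key), so any
stage is independently re-runnable and a rerun of the same config is
bit-identical, which the run manifest (SHA-256 per artifact) makes
checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from polymix._rng import subseed
from polymix.evalrisk import (
    EvalReport,
    harrell_c,
    hazard_per_sd,
    integrated_risk_model,
    net_reclassification,
    odds_per_sd,
    percentile_prevalence,
    risk_equivalent_threshold,
    tail_fraction_scan,
    write_report,
)
from polymix.evalrisk.variance import delta_nagelkerke_r2, liability_r2
from polymix.mix import (
    MixModel,
    fit_mixing_weights,
    flatten_weights,
    stepwise_aic_select,
    tune_best_candidate,
    write_mixmodel,
)
from polymix.mix.glmfit import logit_fit
from polymix.score import score_cohort, standardize_scores
from polymix.score.scoring import ScoreVector
from polymix.shrink import GridConfig, enumerate_grid, write_weightset
from polymix.simcohort import (
    run_gwas,
    simulate_cohort,
    simulate_panel_set,
    simulate_true_effects,
    write_cohort,
    write_ld_panel,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "default_config"]


class TraitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    h2: float = Field(gt=-1e-12, lt=1.0)
    kind: str = "quantitative"  # "binary" (the disease trait) or "quantitative"
    gwas_ancestries: list[str]
    gwas_n: dict[str, int]

    @field_validator("kind")
    @classmethod
    def _kind(cls, v: str) -> str:
        if v not in ("binary", "quantitative"):
            raise ValueError("trait kind must be 'binary' or 'quantitative'")
        return v


class SimulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ancestries: list[str] = ["EUR", "AFR", "SAS"]
    n_blocks: int = Field(default=30, ge=1)
    block_size: tuple[int, int] = (30, 50)
    decay: float = Field(default=0.25, gt=0)
    divergence: float = Field(default=0.15, ge=0, le=1)
    traits: list[TraitConfig] = Field(
        default_factory=lambda: [
            TraitConfig(
                name="cad",
                h2=0.4,
                kind="binary",
                gwas_ancestries=["EUR", "AFR", "SAS"],
                gwas_n={"EUR": 5000, "AFR": 8000, "SAS": 8000},
            ),
            TraitConfig(name="lipids", h2=0.4, gwas_ancestries=["EUR"], gwas_n={"EUR": 8000}),
        ]
    )
    p_causal: float = Field(default=0.05, gt=0, le=1)
    rg_anc: float = Field(default=0.8, ge=-1, le=1)
    rg_trait: float = Field(default=0.6, ge=-1, le=1)
    prevalence: float = Field(default=0.12, gt=0, lt=1)
    incident_rate: float = Field(default=0.01, gt=0)
    incident_log_hr_per_sd: float = 0.4
    comorbidity_log_hr: float = 1.0
    followup_years: float = Field(default=12.0, gt=0)
    target_ancestry: str = "EUR"
    n_train: int = Field(default=4000, ge=100)
    n_validation: int = Field(default=4000, ge=100)

    @property
    def disease_trait(self) -> str:
        for t in self.traits:
            if t.kind == "binary":
                return t.name
        raise ValueError("config needs exactly one binary (disease) trait")


class GridBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    causal_fractions: list[float] | None = None  # None -> the 17 defaults
    h2_scales: list[float] | None = None  # None -> [0.7, 1.0, 1.4]
    sparse: list[bool] | None = None  # None -> [False, True]
    gibbs_iterations: int = Field(default=200, ge=10)
    burn_in: int = Field(default=200, ge=10)
    h2_hat: float | None = Field(default=None, gt=0, lt=1)  # override LD-score estimate

    def to_grid_config(self, seed: int) -> GridConfig:
        kwargs: dict = {"gibbs_iterations": self.gibbs_iterations, "burn_in": self.burn_in, "seed": seed}
        if self.causal_fractions is not None:
            kwargs["causal_fractions"] = self.causal_fractions
        if self.h2_scales is not None:
            kwargs["h2_scales"] = self.h2_scales
        if self.sparse is not None:
            kwargs["sparse_flags"] = self.sparse
        return GridConfig(**kwargs)


class EvaluationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    nri_threshold: float = Field(default=0.075, gt=0, lt=1)
    n_boot: int = Field(default=100, ge=0)
    fold_thresholds: list[float] = [3.0, 4.0, 5.0]
    horizon: float = Field(default=10.0, gt=0)


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    seed: int = 0
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    grid: GridBlock = Field(default_factory=GridBlock)
    evaluation: EvaluationConfig = Field(default_factory=EvaluationConfig)


def default_config(name: str = "default", seed: int = 0) -> PipelineConfig:
    return PipelineConfig(name=name, seed=seed)


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse, default and validate a YAML pipeline config; reject unknown keys."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text()) or {}
    return PipelineConfig.model_validate(raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _finalize(run_dir: Path) -> Path:
    manifest = {
        str(p.relative_to(run_dir)): _sha256(p)
        for p in sorted(run_dir.rglob("*"))
        if p.is_file() and p.name not in ("pipeline.log", "manifest.json")
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return run_dir


def _stage(name: str, run_dir: Path):
    """Context manager logging stage start/end and halting with the stage name."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            self.t0 = time.time()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                logger.error("stage %s: FAILED (%s); artifacts preserved in %s", name, exc, run_dir)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.1fs", name, time.time() - self.t0)
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig, out_dir: str | Path, stop_after: str | None = None) -> Path:
    """Execute the stages in order, persisting artifacts and a hash manifest.

    ``stop_after`` ("simulate", "shrink", "mix", "score") truncates the run
    after that stage; the manifest covers whatever was produced.
    """
    run_dir = Path(out_dir) / config.name
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("polymix")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    sim = config.simulation
    seed = config.seed
    disease = sim.disease_trait
    try:
        (run_dir / "config.yaml").write_text(yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True))

        with _stage("simulate", run_dir):
            panels = simulate_panel_set(
                sim.ancestries, sim.n_blocks, sim.block_size, sim.decay, sim.divergence,
                seed=subseed(seed, "panels"),
            )
            for anc, panel in panels.items():
                write_ld_panel(panel, run_dir / "panels" / anc)
            trait_names = [t.name for t in sim.traits]
            h2_map = {t.name: t.h2 for t in sim.traits}
            effects = simulate_true_effects(
                panels, sim.p_causal, h2_map, sim.rg_anc, sim.rg_trait,
                seed=subseed(seed, "effects"), traits=trait_names,
            )
            clinical_model = {
                "intercept": -3.0,
                "age": 0.05,
                "sex": 0.5,
                "traits": {t.name: 0.3 for t in sim.traits if t.kind == "quantitative"},
            }
            common = dict(
                prevalence_K=sim.prevalence,
                incident_rate=sim.incident_rate,
                followup_years=sim.followup_years,
                disease_trait=disease,
                incident_log_hr_per_sd=sim.incident_log_hr_per_sd,
                comorbidity_log_hr=sim.comorbidity_log_hr,
                clinical_model=clinical_model,
            )
            gwas_sizes: dict[str, int] = {}
            for t in sim.traits:
                for anc, n in t.gwas_n.items():
                    gwas_sizes[anc] = max(gwas_sizes.get(anc, 0), n)
            sumstats: dict[tuple[str, str], object] = {}
            for anc, n in gwas_sizes.items():
                gwas_cohort = simulate_cohort(
                    {anc: panels[anc]}, effects, {anc: n}, seed=subseed(seed, "gwas-cohort", anc), **common
                )
                for t in sim.traits:
                    if anc not in t.gwas_ancestries:
                        continue
                    outcome = "prevalent_case" if t.kind == "binary" else t.name
                    ss = run_gwas(gwas_cohort, outcome, "auto")
                    ss.trait, ss.ancestry = t.name, anc
                    ss.to_tsv(run_dir / "sumstats" / f"{t.name}.{anc}.tsv")
                    sumstats[(t.name, anc)] = ss
            train = simulate_cohort(
                panels, effects, {sim.target_ancestry: sim.n_train}, seed=subseed(seed, "train"), **common
            )
            valid = simulate_cohort(
                panels, effects, {sim.target_ancestry: sim.n_validation}, seed=subseed(seed, "valid"), **common
            )
            write_cohort(train, run_dir / "cohorts" / "train")
            write_cohort(valid, run_dir / "cohorts" / "validation")
        if stop_after == "simulate":
            return _finalize(run_dir)

        with _stage("shrink", run_dir):
            candidates: dict[tuple[str, str], list] = {}
            for (trait, anc), ss in sumstats.items():
                grid_cfg = config.grid.to_grid_config(subseed(seed, "grid", trait, anc))
                ws_list = enumerate_grid(ss, panels[anc], grid_cfg, h2_hat=config.grid.h2_hat)
                candidates[(trait, anc)] = ws_list
                for i, ws in enumerate(ws_list):
                    write_weightset(ws, run_dir / "weights" / "candidates" / f"{trait}.{anc}.{i:03d}.tsv")
        if stop_after == "shrink":
            return _finalize(run_dir)

        with _stage("mix", run_dir):
            covs = train.covariate_matrix()
            y_train = train.data["prevalent_case"].to_numpy()
            tuned: dict[tuple[str, str], object] = {}
            for key, ws_list in candidates.items():
                best, _summary = tune_best_candidate(ws_list, train)
                tuned[key] = best
                write_weightset(best, run_dir / "weights" / "tuned" / f"{key[0]}.{key[1]}.tsv")

            layer1_models: dict[str, MixModel] = {}
            layer1_train_scores: dict[str, np.ndarray] = {}
            layer1_constants: dict[tuple[str, str], object] = {}
            for t in sim.traits:
                comp_scores = {}
                comp_consts = {}
                for anc in t.gwas_ancestries:
                    sv, consts, _ = score_cohort(train, tuned[(t.name, anc)], score_id=f"{t.name}|{anc}")
                    comp_scores[anc] = sv.standardized
                    comp_consts[anc] = consts
                    layer1_constants[(t.name, anc)] = consts
                frame = pd.DataFrame(comp_scores, index=covs.index)
                selected, trace = stepwise_aic_select(frame, y_train, covs)
                if not selected:  # keep at least the best single component
                    selected = [frame.columns[0]]
                model = fit_mixing_weights(
                    frame[selected], y_train, covs,
                    constants=comp_consts, layer=1, components=list(frame.columns), aic_trace=trace,
                )
                layer1_models[t.name] = model
                write_mixmodel(model, run_dir / "mixmodels" / f"layer1.{t.name}.json")
                layer1_train_scores[t.name] = model.combine(frame)

            l2_frame_raw = pd.DataFrame(layer1_train_scores, index=covs.index)
            l2_consts = {}
            l2_std = {}
            for t_name in l2_frame_raw.columns:
                sv = ScoreVector(
                    sample_ids=train.data["sample_id"].to_numpy(),
                    raw=l2_frame_raw[t_name].to_numpy(),
                    ancestry=train.data["ancestry"].to_numpy(),
                    score_id=t_name,
                )
                sv2, consts = standardize_scores(sv, train.pc_matrix())
                l2_std[t_name] = sv2.standardized
                l2_consts[t_name] = consts
            l2_frame = pd.DataFrame(l2_std, index=covs.index)
            l2_selected, l2_trace = stepwise_aic_select(l2_frame, y_train, covs)
            if disease not in l2_selected:
                l2_selected = [disease] + l2_selected  # the target trait always contributes
            layer2 = fit_mixing_weights(
                l2_frame[l2_selected], y_train, covs,
                constants=l2_consts, layer=2, components=list(l2_frame.columns), aic_trace=l2_trace,
            )
            write_mixmodel(layer2, run_dir / "mixmodels" / "layer2.json")

            final_ws = flatten_weights(layer1_models, layer2, tuned)
            final_ws.metadata["name"] = config.name
            write_weightset(final_ws, run_dir / "weights" / "final.tsv")
        if stop_after == "mix":
            return _finalize(run_dir)

        with _stage("score", run_dir):
            sv_train, final_consts, _ = score_cohort(train, final_ws, score_id="final")
            sv_valid, _, _ = score_cohort(valid, final_ws, constants=final_consts, score_id="final")
            (run_dir / "scores").mkdir(exist_ok=True)
            sv_valid.to_frame().to_csv(
                run_dir / "scores" / "validation.tsv", sep="\t", index=False, float_format="%.10g"
            )
            sv_train.to_frame().to_csv(
                run_dir / "scores" / "train.tsv", sep="\t", index=False, float_format="%.10g"
            )
        if stop_after == "score":
            return _finalize(run_dir)

        with _stage("evaluate", run_dir):
            report = evaluate_score(
                sv_valid.standardized, valid, sim.prevalence, config.evaluation,
                seed=subseed(seed, "evaluate"),
            )
            write_report(report, run_dir / "report")

        return _finalize(run_dir)
    finally:
        root.removeHandler(handler)
        handler.close()


def evaluate_score(
    score_std: np.ndarray,
    cohort,
    prevalence: float,
    eval_config: EvaluationConfig | None = None,
    seed: int = 0,
) -> EvalReport:
    """Run the full evaluation battery for one standardized score."""
    cfg = eval_config or EvaluationConfig()
    data = cohort.data
    report = EvalReport(seeds={"evaluate": int(seed)})
    report.odds_per_sd = odds_per_sd(score_std, cohort)
    report.hazard_per_sd = hazard_per_sd(score_std, cohort)
    d_r2 = delta_nagelkerke_r2(score_std, cohort)
    report.delta_nagelkerke_r2 = d_r2
    report.liability_r2 = liability_r2(d_r2, prevalence, float(data["prevalent_case"].mean()))

    report.percentile_prevalence = percentile_prevalence(score_std, data["prevalent_case"].to_numpy())
    report.tail_fractions = tail_fraction_scan(
        score_std,
        data["prevalent_case"].to_numpy(),
        cfg.fold_thresholds,
        direction="top",
        covariates=cohort.covariate_matrix(),
    )
    req, _trace = risk_equivalent_threshold(score_std, cohort, data["prevalent_case"].to_numpy())
    report.risk_equivalent_percentile = req

    incident_mask = (data["prevalent_case"] == 0).to_numpy()
    clinical = data["clinical_risk_10yr"].to_numpy()
    y10 = (
        (data["incident_case"].to_numpy() == 1)
        & (data["follow_up_time"].to_numpy() <= cfg.horizon)
    ).astype(int)
    # "new" risk: clinical estimator augmented with the score, refit on the horizon outcome
    aug = pd.DataFrame({"clinical": clinical[incident_mask], "score": score_std[incident_mask]})
    fit = logit_fit(aug, y10[incident_mask])
    lin = (
        fit.params["const"]
        + fit.params["clinical"] * clinical[incident_mask]
        + fit.params["score"] * score_std[incident_mask]
    )
    new_risk = 1.0 / (1.0 + np.exp(-lin))
    report.nri = net_reclassification(
        clinical[incident_mask], new_risk, y10[incident_mask],
        threshold=cfg.nri_threshold, n_boot=cfg.n_boot, seed=seed,
    )
    report.harrell_c = harrell_c(
        new_risk,
        data.loc[incident_mask, "follow_up_time"].to_numpy(),
        data.loc[incident_mask, "incident_case"].to_numpy(),
    )
    integrated = integrated_risk_model(score_std, clinical, cohort, horizon=cfg.horizon)
    report.interaction_coef = integrated.interaction_coef
    report.interaction_p = integrated.interaction_p
    report.incidence_grid = integrated.incidence_grid
    return report
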