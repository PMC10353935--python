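"""Fitted mixing models and their structured-text serialization."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from polymix.mix.glmfit import logit_fit
from polymix.score.scoring import StandardizationConstants

__all__ = ["MixModel", "fit_mixing_weights", "write_mixmodel", "read_mixmodel"]


@dataclass
class MixModel:
    """A fitted layer-1 (within-trait) or layer-2 (across-trait) combination."""

    layer: int
    components: list[str]
    selected: list[str]
    beta: dict[str, float]  # mixing coefficient per selected component (per SD)
    covariate_coefs: dict[str, float]
    constants: dict[str, StandardizationConstants]
    aic_trace: list[float] = field(default_factory=list)

    def validate(self) -> None:
        if not set(self.selected) <= set(self.components):
            raise ValueError("selected components must be a subset of components")
        if any(b > a + 1e-9 for a, b in zip(self.aic_trace, self.aic_trace[1:])):
            raise ValueError("AIC trace must be non-increasing along accepted steps")
        if not all(np.isfinite(v) for v in self.beta.values()):
            raise ValueError("mixing coefficients must be finite")

    def combine(self, standardized_scores: pd.DataFrame) -> np.ndarray:
        """Linear combination of standardized component scores by the mixing betas."""
        out = np.zeros(len(standardized_scores))
        for c in self.selected:
            out = out + self.beta[c] * standardized_scores[c].to_numpy()
        return out


def fit_mixing_weights(
    selected_scores: pd.DataFrame,
    outcome: np.ndarray,
    covariates: pd.DataFrame | None = None,
    constants: dict[str, StandardizationConstants] | None = None,
    layer: int = 1,
    components: list[str] | None = None,
    aic_trace: list[float] | None = None,
) -> MixModel:
    """One logistic fit of outcome on covariates + selected standardized scores.

    The score coefficients become the mixing weights; covariate
    coefficients are stored but never used for weight flattening.
    """
    comps = list(selected_scores.columns)
    covs = covariates if covariates is not None else pd.DataFrame(index=selected_scores.index)
    design = pd.concat([covs, selected_scores], axis=1)
    fit = logit_fit(design, outcome)
    beta = {c: float(fit.params[c]) for c in comps}
    cov_coefs = {c: float(fit.params[c]) for c in fit.params.index if c not in comps}
    model = MixModel(
        layer=layer,
        components=components or comps,
        selected=comps,
        beta=beta,
        covariate_coefs=cov_coefs,
        constants=constants or {},
        aic_trace=aic_trace or [fit.aic],
    )
    model.validate()
    return model


def _constants_to_dict(c: StandardizationConstants) -> dict:
    return {
        "pc_coefs": {g: list(map(float, v)) for g, v in c.pc_coefs.items()},
        "mean": c.mean,
        "sd": c.sd,
    }


def _constants_from_dict(d: dict) -> StandardizationConstants:
    return StandardizationConstants(
        pc_coefs={g: np.asarray(v, dtype=float) for g, v in d["pc_coefs"].items()},
        mean={g: float(v) for g, v in d["mean"].items()},
        sd={g: float(v) for g, v in d["sd"].items()},
    )


def write_mixmodel(model: MixModel, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "layer": model.layer,
        "components": model.components,
        "selected": model.selected,
        "beta": model.beta,
        "covariate_coefs": model.covariate_coefs,
        "constants": {c: _constants_to_dict(v) for c, v in model.constants.items()},
        "aic_trace": model.aic_trace,
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def read_mixmodel(path: str | Path) -> MixModel:
    payload = json.loads(Path(path).read_text())
    model = MixModel(
        layer=int(payload["layer"]),
        components=list(payload["components"]),
        selected=list(payload["selected"]),
        beta={k: float(v) for k, v in payload["beta"].items()},
        covariate_coefs={k: float(v) for k, v in payload["covariate_coefs"].items()},
        constants={c: _constants_from_dict(v) for c, v in payload["constants"].items()},
        aic_trace=[float(v) for v in payload["aic_trace"]],
    )
    model.validate()
    return model
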