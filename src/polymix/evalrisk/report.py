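"""Evaluation report assembly: machine-readable JSON plus TSV tables."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from polymix.evalrisk.association import AssocResult
from polymix.evalrisk.concordance import ConcordanceResult
from polymix.evalrisk.reclassification import NRIResult

__all__ = ["EvalReport", "write_report"]


@dataclass
class EvalReport:
    """Container for whatever subset of the evaluation battery was run."""

    odds_per_sd: AssocResult | None = None
    hazard_per_sd: AssocResult | None = None
    delta_nagelkerke_r2: float | None = None
    liability_r2: float | None = None
    harrell_c: ConcordanceResult | None = None
    nri: dict[str, NRIResult] | None = None
    percentile_prevalence: pd.DataFrame | None = None
    tail_fractions: pd.DataFrame | None = None
    risk_equivalent_percentile: int | None = None
    interaction_coef: float | None = None
    interaction_p: float | None = None
    incidence_grid: pd.DataFrame | None = None
    seeds: dict[str, int] = field(default_factory=dict)

    def summary_dict(self) -> dict:
        out: dict = {"seeds": self.seeds}
        for name in ("odds_per_sd", "hazard_per_sd", "harrell_c"):
            val = getattr(self, name)
            if val is not None:
                d = asdict(val)
                d.pop("model", None)
                out[name] = d
        for name in (
            "delta_nagelkerke_r2",
            "liability_r2",
            "risk_equivalent_percentile",
            "interaction_coef",
            "interaction_p",
        ):
            if getattr(self, name) is not None:
                out[name] = getattr(self, name)
        if self.nri is not None:
            out["nri"] = {
                k: {"event": v.event, "non_event": v.non_event, "overall": v.overall, "ci": v.ci}
                for k, v in self.nri.items()
            }
        return out


def write_report(report: EvalReport, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "summary.json").write_text(json.dumps(report.summary_dict(), indent=1, sort_keys=True))
    for name in ("percentile_prevalence", "tail_fractions", "incidence_grid"):
        table = getattr(report, name)
        if table is not None:
            table.to_csv(directory / f"{name}.tsv", sep="\t", index=False, float_format="%.10g")
    return directory
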