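"""Variant-level scoring weights with provenance metadata.

Serialized in a PGS-Catalog-style scoring format: ``#key=value`` header
comment lines, then tab-separated columns rsID, chr_name, chr_position,
effect_allele, other_allele, effect_weight.  Floats are written with
repr-level precision so files round-trip bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["WeightSet", "write_weightset", "read_weightset"]

_COLUMNS = ["rsID", "chr_name", "chr_position", "effect_allele", "other_allele", "effect_weight"]


@dataclass
class WeightSet:
    """Per-allele scoring weights for one candidate or combined score."""

    table: pd.DataFrame  # columns _COLUMNS
    metadata: dict = field(default_factory=dict)  # trait, ancestry, p, s, sparse, ...

    def __len__(self) -> int:
        return len(self.table)

    @property
    def weights(self) -> np.ndarray:
        return self.table["effect_weight"].to_numpy()

    def validate(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"weight set missing columns: {missing}")
        if not np.all(np.isfinite(self.table["effect_weight"])):
            raise ValueError("weights must be finite")
        ids = self.table["rsID"]
        if ids.duplicated().any():
            raise ValueError("variant ids must be unique")
        if (self.table["effect_allele"] == self.table["other_allele"]).any():
            raise ValueError("effect_allele must differ from other_allele")

    def sort_key(self) -> tuple:
        """Tie-break ordering for candidate selection: smaller p, smaller s, non-sparse."""
        m = self.metadata
        return (m.get("p", np.inf), m.get("s", np.inf), bool(m.get("sparse", False)))


def write_weightset(ws: WeightSet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k in sorted(ws.metadata):
            fh.write(f"#{k}={ws.metadata[k]}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for row in ws.table.itertuples(index=False):
            fh.write(
                f"{row.rsID}\t{row.chr_name}\t{row.chr_position}\t"
                f"{row.effect_allele}\t{row.other_allele}\t{row.effect_weight!r}\n"
            )
    return path


def _parse_meta(value: str):
    if value in ("True", "False"):
        return value == "True"
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value


def read_weightset(path: str | Path) -> WeightSet:
    path = Path(path)
    metadata = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].rstrip("\n").partition("=")
            metadata[k] = _parse_meta(v)
    table = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        float_precision="round_trip",
        dtype={"rsID": str, "effect_allele": str, "other_allele": str, "effect_weight": float},
    )
    ws = WeightSet(table=table, metadata=metadata)
    ws.validate()
    return ws
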