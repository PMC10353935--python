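"""Flatten a two-layer mixing model into one variant-level WeightSet.

Final per-variant weight:

    w_j = sum_t (beta2_t / sd_t) * sum_a (beta1_{t,a} / sd_{t,a}) * w_{t,a,j}

over the union of component variants (absent weight = 0), after
harmonizing alleles to a single reference orientation (the first
orientation seen per variant; swapped or strand-complement components
contribute with negated weight, the affine offset being absorbed by the
downstream standardization).  Scoring a cohort with the flattened set is
affine-equivalent to the explicit two-layer combination of component
scores.
"""

from __future__ import annotations

import logging

import pandas as pd

from polymix.mix.mixmodel import MixModel
from polymix.shrink.weights import WeightSet

__all__ = ["flatten_weights"]

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _orient(ea: str, oa: str, ref_ea: str, ref_oa: str) -> float | None:
    """+1 if same orientation as reference, -1 if swapped, None if irreconcilable."""
    cea, coa = _COMPLEMENT.get(ea), _COMPLEMENT.get(oa)
    if (ea, oa) == (ref_ea, ref_oa) or (cea, coa) == (ref_ea, ref_oa):
        return 1.0
    if (oa, ea) == (ref_ea, ref_oa) or (coa, cea) == (ref_ea, ref_oa):
        return -1.0
    return None


def flatten_weights(
    mix_models_layer1: dict[str, MixModel],
    mix_model_layer2: MixModel,
    component_weightsets: dict[tuple[str, str], WeightSet],
) -> WeightSet:
    """Collapse layer-1 + layer-2 mixing into a single scoring file.

    ``mix_models_layer1`` maps trait -> layer-1 model whose component ids
    are ancestry labels; ``component_weightsets`` maps (trait, ancestry)
    -> the tuned candidate WeightSet.  Component SDs come from the
    training standardization constants stored on each model.
    """
    acc: dict[str, dict] = {}
    dropped = 0
    for trait in mix_model_layer2.selected:
        b2 = mix_model_layer2.beta[trait]
        sd2 = mix_model_layer2.constants[trait].pooled_sd()
        l1 = mix_models_layer1[trait]
        for anc in l1.selected:
            b1 = l1.beta[anc]
            sd1 = l1.constants[anc].pooled_sd()
            factor = (b2 / sd2) * (b1 / sd1)
            ws = component_weightsets[(trait, anc)]
            for row in ws.table.itertuples(index=False):
                entry = acc.get(row.rsID)
                if entry is None:
                    acc[row.rsID] = {
                        "chr_name": row.chr_name,
                        "chr_position": row.chr_position,
                        "effect_allele": row.effect_allele,
                        "other_allele": row.other_allele,
                        "weight": factor * row.effect_weight,
                    }
                else:
                    sign = _orient(
                        row.effect_allele, row.other_allele, entry["effect_allele"], entry["other_allele"]
                    )
                    if sign is None:
                        entry["conflict"] = True
                        dropped += 1
                        continue
                    entry["weight"] += sign * factor * row.effect_weight
    if dropped:
        logger.warning("dropped %d variant contributions with irreconcilable alleles", dropped)
    rows = [
        (rsid, e["chr_name"], e["chr_position"], e["effect_allele"], e["other_allele"], e["weight"])
        for rsid, e in acc.items()
        if not e.get("conflict")
    ]
    table = pd.DataFrame(
        rows,
        columns=["rsID", "chr_name", "chr_position", "effect_allele", "other_allele", "effect_weight"],
    )
    out = WeightSet(
        table=table,
        metadata={
            "trait": "combined",
            "layer2_components": ",".join(mix_model_layer2.selected),
            "provenance": "flattened two-layer mixing model",
        },
    )
    out.validate()
    return out
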