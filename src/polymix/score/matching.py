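"""Align a WeightSet's alleles to a cohort's variant orientation.

Resolution per shared variant id:

- exact match (effect/other equal): kept as-is;
- swapped (effect/other reversed): kept, dosage complemented (2 - d);
- strand flip (base-complement of either orientation): resolved likewise;
- strand-ambiguous weights (A/T or C/G pairs): dropped;
- anything irreconcilable or absent from the cohort: dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from polymix.shrink.weights import WeightSet

__all__ = ["MatchReport", "match_alleles"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class MatchReport:
    kept: int = 0
    swapped: int = 0
    flipped: int = 0
    dropped_ambiguous: int = 0
    dropped_unmatched: int = 0

    @property
    def total_used(self) -> int:
        return self.kept + self.swapped + self.flipped


def match_alleles(weights: WeightSet, cohort_variants: pd.DataFrame) -> tuple[pd.DataFrame, MatchReport]:
    """Return an aligned weight table plus a match report.

    ``cohort_variants`` needs columns variant_id, effect_allele,
    other_allele (the cohort's dosage-counted allele first).  The aligned
    table has columns: variant_index (row in the cohort variant table /
    dosage column), weight, complement (True when the cohort dosage must
    be complemented as ``2 - d``).
    """
    cv = cohort_variants.reset_index(drop=True)
    lookup = {v: i for i, v in enumerate(cv["variant_id"])}
    report = MatchReport()
    rows = []
    for w in weights.table.itertuples(index=False):
        pair = frozenset((w.effect_allele, w.other_allele))
        if pair in _AMBIGUOUS:
            report.dropped_ambiguous += 1
            continue
        idx = lookup.get(w.rsID)
        if idx is None:
            report.dropped_unmatched += 1
            continue
        a1, a2 = cv.at[idx, "effect_allele"], cv.at[idx, "other_allele"]
        ew, ow = w.effect_allele, w.other_allele
        cew, cow = _COMPLEMENT.get(ew), _COMPLEMENT.get(ow)
        if (ew, ow) == (a1, a2):
            report.kept += 1
            rows.append((idx, w.effect_weight, False))
        elif (ew, ow) == (a2, a1):
            report.swapped += 1
            rows.append((idx, w.effect_weight, True))
        elif (cew, cow) == (a1, a2):
            report.flipped += 1
            rows.append((idx, w.effect_weight, False))
        elif (cew, cow) == (a2, a1):
            report.flipped += 1
            rows.append((idx, w.effect_weight, True))
        else:
            report.dropped_unmatched += 1
    if not rows:
        raise ValueError("no weight-set variants could be matched to the cohort")
    aligned = pd.DataFrame(rows, columns=["variant_index", "weight", "complement"])
    aligned["variant_index"] = aligned["variant_index"].astype(int)
    aligned["complement"] = aligned["complement"].astype(bool)
    return aligned, report
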