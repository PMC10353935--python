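"""Net reclassification improvement, categorical and continuous.

Categorical (two classes split at the risk threshold):

    event NRI     = P(up | event) - P(down | event)
    non-event NRI = P(down | non-event) - P(up | non-event)
    overall       = event NRI + non-event NRI

Continuous NRI uses the sign of the risk change instead of category
crossings.  Percentile bootstrap CIs resample individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from polymix._rng import substream

__all__ = ["NRIResult", "net_reclassification"]


@dataclass
class NRIResult:
    event: float
    non_event: float
    overall: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    kind: str = "categorical"

    def validate(self) -> None:
        if abs(self.overall - (self.event + self.non_event)) > 1e-12:
            raise ValueError("overall NRI must equal event + non-event components")


def _components(old: np.ndarray, new: np.ndarray, y: np.ndarray, threshold: float | None):
    if threshold is not None:
        up = (old < threshold) & (new >= threshold)
        down = (old >= threshold) & (new < threshold)
    else:
        up = new > old
        down = new < old
    ev = y == 1
    ne = ~ev
    if ev.sum() == 0 or ne.sum() == 0:
        raise ValueError("need both events and non-events for NRI")
    event = (up[ev].mean() - down[ev].mean())
    non_event = (down[ne].mean() - up[ne].mean())
    return float(event), float(non_event)


def net_reclassification(
    old_risk: np.ndarray,
    new_risk: np.ndarray,
    outcome: np.ndarray,
    threshold: float = 0.075,
    n_boot: int = 100,
    seed: int = 0,
) -> dict[str, NRIResult]:
    """Categorical and continuous NRI with bootstrap percentile CIs.

    Returns ``{"categorical": NRIResult, "continuous": NRIResult}``.
    """
    old = np.asarray(old_risk, dtype=float)
    new = np.asarray(new_risk, dtype=float)
    y = np.asarray(outcome).astype(int)
    for name, r in (("old_risk", old), ("new_risk", new)):
        if np.any((r < 0) | (r > 1)):
            raise ValueError(f"{name} must lie in [0, 1]")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")

    out: dict[str, NRIResult] = {}
    rng = substream(seed, "nri-bootstrap")
    n = len(y)
    boot_idx = [rng.integers(0, n, size=n) for _ in range(n_boot)] if n_boot > 0 else []
    for kind, thr in (("categorical", threshold), ("continuous", None)):
        ev, ne = _components(old, new, y, thr)
        res = NRIResult(event=ev, non_event=ne, overall=ev + ne, kind=kind)
        if boot_idx:
            samples = {"event": [], "non_event": [], "overall": []}
            for idx in boot_idx:
                try:
                    bev, bne = _components(old[idx], new[idx], y[idx], thr)
                except ValueError:
                    continue
                samples["event"].append(bev)
                samples["non_event"].append(bne)
                samples["overall"].append(bev + bne)
            res.ci = {
                k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
                for k, v in samples.items()
                if v
            }
        res.validate()
        out[kind] = res
    return out
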