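"""Deterministic seed fan-out.

A single user-facing seed is expanded into independent per-stage /
per-substream generators through ``numpy.random.SeedSequence`` with an
explicit spawn key, so any stage can be re-run in isolation and still see
the same stream.  String keys are folded in via CRC32 so labels (ancestry
names, trait names) participate in the key deterministically across runs.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "subseed"]


def _fold(key: int | str) -> int:
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    return int(key)


def substream(seed: int, *keys: int | str) -> np.random.Generator:
    """Return a Generator for ``(seed, *keys)``, independent across keys."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(_fold(k) for k in keys))
    return np.random.default_rng(ss)


def subseed(seed: int, *keys: int | str) -> int:
    """A 32-bit integer seed derived from ``(seed, *keys)`` (for numba kernels)."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(_fold(k) for k in keys))
    return int(ss.generate_state(1, dtype=np.uint32)[0])
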