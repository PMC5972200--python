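"""Deterministic seed fan-out.

A single master seed is expanded into per-stage (and per-subject) seeds by
hashing the stage name, so adding a new stage to the pipeline never perturbs
the random draws of existing stages.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31 - 1


def stage_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Derive a stable sub-seed (< 2**31) from a master seed and stage name."""
    h = zlib.crc32(stage.encode("utf-8"))
    return (master_seed * 1_000_003 + h * 9_176 + index * 7_919) % _MOD


def stage_rng(master_seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Generator seeded from :func:`stage_seed`."""
    return np.random.default_rng(stage_seed(master_seed, stage, index))
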