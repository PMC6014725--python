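"""Seed handling: one master seed expands to independent per-stage streams."""

from __future__ import annotations

import zlib

import numpy as np

RngLike = "int | np.random.Generator | None"


def stage_rng(seed: int | None, stage: str) -> np.random.Generator:
    """Generator for a named pipeline stage, decorrelated from other stages.

    The stage name is hashed (CRC-32) into the seed sequence so that e.g.
    scene generation and rendering draw from independent streams even under
    the same master seed.
    """
    key = zlib.crc32(stage.encode("utf-8"))
    if seed is None:
        ss = np.random.SeedSequence(spawn_key=(key,))
    else:
        ss = np.random.SeedSequence(int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)


def as_rng(seed, stage: str = "default") -> np.random.Generator:
    """Coerce an int seed, Generator, or None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return stage_rng(seed, stage)
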