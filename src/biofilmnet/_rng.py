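"""Seed handling: one root seed, split per stage by stable stage names."""

from __future__ import annotations

import zlib

import numpy as np


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Generator for a named pipeline stage, derived from the root seed.

    Distinct stage names yield independent streams; the same (seed, stage)
    pair always yields the same stream.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode("utf-8"))])
    )
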