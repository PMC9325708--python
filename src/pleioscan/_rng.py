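"""Seed plumbing: one global seed, per-stage derived substreams.

Stages are named; the stage name is hashed into the seed sequence so any
stage can be re-run in isolation and still produce the bytes it would have
produced inside a full run.
"""

from __future__ import annotations

import zlib

import numpy as np


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return a Generator deterministically derived from ``seed`` and ``stage``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())]))


def stage_seed(seed: int, stage: str) -> int:
    """A plain integer sub-seed (< 2**31) for APIs that want one."""
    return int(stage_rng(seed, stage).integers(0, 2**31 - 1))
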