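"""Deterministic named random sub-streams.

A single master seed drives every stochastic stage of the pipeline.  Each
stage derives its own :class:`numpy.random.Generator` from the master seed
combined with a stable hash of the stage name, so adding a new stage never
perturbs the streams of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(master_seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Return the generator for stage ``name`` under ``master_seed``.

    ``index`` distinguishes repeated draws within a stage (e.g. one stream
    per child).
    """
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, key, int(index)])
    return np.random.default_rng(ss)


def spawn_seed(master_seed: int, name: str, index: int = 0) -> int:
    """A 31-bit integer seed derived like :func:`substream` (for APIs that
    take plain seeds)."""
    return int(substream(master_seed, name, index).integers(0, 2**31 - 1))
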