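"""Deterministic seed splitting.

Every stage of the pipeline draws from a named substream of one global
integer seed, so stages stay reproducible even when run in isolation or
toggled off.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "subseed"]


def subseed(seed: int, name: str) -> int:
    """Derive a stable 31-bit integer seed for the named substream."""
    return (int(seed) * 0x9E3779B1 + zlib.crc32(name.encode())) % (2**31 - 1)


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator seeded from ``seed`` and the substream ``name``.

    The mapping is a fixed hash; distinct names give independent streams,
    and the same (seed, name) pair always yields the same stream.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())]))
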