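"""Seed plumbing.

One user-facing seed per invocation is expanded into independent substreams
keyed by stable string labels, so the order in which pipeline stages consume
randomness never perturbs any other stage.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def substream_seed(seed: int, label: str) -> np.random.SeedSequence:
    """Derive a child seed sequence from ``seed`` and a stage label."""
    return np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode("utf-8"))])


def substream(seed: int, label: str) -> np.random.Generator:
    """A generator seeded deterministically by ``(seed, label)``."""
    return np.random.default_rng(substream_seed(seed, label))
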