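"""Seed plumbing: one top-level seed, named substreams per generator."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of a top-level seed.

    Streams for distinct names are statistically independent (distinct
    SeedSequence entropy) and reproducible across runs and platforms.
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))
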