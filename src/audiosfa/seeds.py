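"""Deterministic seed derivation for independent pipeline stages.

A single master seed is fanned out to named streams so any stage can be
rerun in isolation: ``derive(master, "clutter", pair_idx, repeat)`` hashes
the token tuple with CRC-32 and mixes it with the master via NumPy's
SeedSequence. Derived seeds are kept below 2**31 so they are valid inputs
everywhere an int seed is accepted.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive", "derive_rng"]


def derive(master: int, *tokens) -> int:
    """Stable child seed for the stream named by ``tokens``."""
    h = zlib.crc32(repr(tokens).encode("utf-8"))
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, h])
    return int(ss.generate_state(1)[0] % (2**31))


def derive_rng(master: int, *tokens) -> np.random.Generator:
    return np.random.default_rng(derive(master, *tokens))
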