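"""Stable named sub-seeding.

All stochastic components derive their generator from a single root seed plus a
tuple of string names, so partial re-runs (e.g. re-simulating one sample) draw
the same numbers as a full run.
"""

from __future__ import annotations

import zlib

import numpy as np


def named_rng(seed: int, *names: object) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and a stable hash of ``names``.

    The name hash uses CRC32, which is stable across processes and Python
    versions (unlike ``hash()``).
    """
    key = [int(seed) & 0x7FFFFFFF]
    key.extend(zlib.crc32(str(n).encode("utf-8")) for n in names)
    return np.random.default_rng(np.random.SeedSequence(key))
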