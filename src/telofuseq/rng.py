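"""Named, independent random streams derived from one root seed.

Every generator in the package draws from ``stream(seed, name)``. Streams are
derived with :class:`numpy.random.SeedSequence` using a stable CRC32 hash of
the stream name as the spawn key, so adding a new generator never perturbs
the draws of an existing one, and a fixed (seed, name) pair is byte-stable
across runs and platforms.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream(seed: int, name: str) -> np.random.Generator:
    """Return the independent generator for ``name`` under root ``seed``."""
    if seed < 0:
        raise ValueError("seed must be non-negative")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))
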