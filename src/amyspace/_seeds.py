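"""Deterministic seed derivation.

Every source of randomness in the package flows from a single root seed.
Sub-streams are derived through ``numpy.random.SeedSequence`` spawn keys
built from a stable hash of a human-readable path, e.g.
``rng_for(seed, "subject", 3, "metric", "fa")``.  The derivation depends
only on the root seed and the path, never on call order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["rng_for", "seed_for"]


def _key(parts) -> tuple[int, ...]:
    out = []
    for p in parts:
        if isinstance(p, (int, np.integer)):
            out.append(int(p) & 0xFFFFFFFF)
        else:
            out.append(zlib.crc32(str(p).encode("utf-8")))
    return tuple(out)


def rng_for(root_seed: int, *path) -> np.random.Generator:
    """A Generator for the sub-stream identified by ``path`` under ``root_seed``."""
    ss = np.random.SeedSequence(int(root_seed), spawn_key=_key(path))
    return np.random.Generator(np.random.PCG64(ss))


def seed_for(root_seed: int, *path) -> int:
    """A plain integer seed (< 2**31) derived the same way as :func:`rng_for`."""
    ss = np.random.SeedSequence(int(root_seed), spawn_key=_key(path))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
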