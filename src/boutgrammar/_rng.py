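"""Deterministic random-number plumbing.

All stochastic stages draw from ``numpy.random.Generator`` objects derived
from a single master seed through :func:`child_rng`, so that per-animal work
can be farmed out to parallel workers while remaining bit-identical to a
serial run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng", "as_rng"]


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        if key < 0:
            raise ValueError("seed keys must be non-negative")
        return int(key)
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    raise TypeError(f"unsupported seed key type: {type(key)!r}")


def child_seed(master_seed: int, *keys) -> np.random.SeedSequence:
    """A seed sequence derived from ``master_seed`` and a stable key path.

    Keys may be non-negative integers or strings (hashed with CRC32, which is
    stable across processes and Python versions, unlike ``hash``).
    """
    return np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=tuple(_key_to_int(k) for k in keys)
    )


def child_rng(master_seed: int, *keys) -> np.random.Generator:
    """A generator derived deterministically from a master seed and key path."""
    return np.random.default_rng(child_seed(master_seed, *keys))


def as_rng(seed_or_rng) -> np.random.Generator:
    """Coerce an int seed, SeedSequence, Generator, or None to a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
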