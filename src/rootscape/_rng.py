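"""Seed-substream derivation.

All generators in the package are pure functions of (config, seed).  To avoid
cross-coupling between stages that share a master seed, each operation derives
its own substream by hashing the operation name into the seed sequence.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "derive_seed"]


def derive_seed(master_seed: int, name: str) -> int:
    """Derive a stable 31-bit child seed from a master seed and a stream name."""
    digest = hashlib.sha256(f"{master_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Return an independent ``numpy.random.Generator`` for one named operation."""
    return np.random.default_rng(derive_seed(master_seed, name))
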