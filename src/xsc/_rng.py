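"""Deterministic seed derivation.

Every stochastic stage takes one integer seed and, where it operates on
independent blocks (per species, per cell type, per target gene), derives a
substream per block from a stable hash of the block key. Adding or removing
a block therefore never perturbs the draws of the others.
"""

from __future__ import annotations

import hashlib

import numpy as np


def _key_hash(*parts: object) -> int:
    text = "\x1f".join(str(p) for p in parts)
    digest = hashlib.blake2b(text.encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "little")


def substream(seed: int, *key: object) -> np.random.Generator:
    """Generator for the substream identified by (seed, key...)."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, _key_hash(*key)])


def child_seed(seed: int, *key: object) -> int:
    """A derived integer seed below 2**31, stable in the key."""
    return (_key_hash(*key) ^ (int(seed) & 0x7FFFFFFF)) & 0x7FFFFFFF
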