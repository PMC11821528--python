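"""Seed-stream management.

Every source of randomness in the package derives from one root integer seed
via :func:`rng_for`.  Each consumer names its stream with a path of labels
(e.g. ``rng_for(seed, "genotypes")`` or ``rng_for(seed, "gwas", trait)``);
labels are hashed (CRC-32) into a ``numpy`` ``SeedSequence`` spawn key, so
streams are independent, reproducible, and insensitive to the order in which
stages execute.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "rng_for"]


def child_seed(root_seed: int, *path) -> np.random.SeedSequence:
    """SeedSequence for the stream named by ``path`` under ``root_seed``."""
    key = tuple(zlib.crc32(str(p).encode("utf8")) for p in path)
    return np.random.SeedSequence(entropy=int(root_seed), spawn_key=key)


def rng_for(root_seed: int, *path) -> np.random.Generator:
    """Generator for the stream named by ``path`` under ``root_seed``."""
    return np.random.default_rng(child_seed(root_seed, *path))
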