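"""Named, reproducible random substreams derived from one master seed.

Every stochastic stage draws from ``substream(master_seed, name)`` so that a
single integer reproduces the whole artefact byte-for-byte, and adding a new
consumer of randomness never perturbs existing streams.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def _name_key(name: str) -> int:
    # crc32 is stable across processes, unlike the builtin hash().
    return zlib.crc32(name.encode("utf-8"))


def substream(master_seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Return a Generator for the named substream of ``master_seed``."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(_name_key(name), index))
    return np.random.default_rng(ss)


def substream_seed(master_seed: int, name: str, index: int = 0) -> int:
    """A derived integer seed, for APIs that take a seed rather than a Generator."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(_name_key(name), index))
    return int(ss.generate_state(1, dtype=np.uint64)[0])
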