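"""Deterministic per-stage random substreams.

Every source of randomness in the package is a :class:`numpy.random.Generator`
derived from a single user-supplied master seed plus a stage name (and, for
batch operations, an item name such as a database name).  Names are hashed
with CRC32 so the derivation is stable across interpreter runs and platforms
— Python's builtin ``hash`` is salted per process and must not be used here.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _name_key(name: str) -> int:
    return zlib.crc32(name.encode("utf-8"))


def substream(master_seed: int, *names: str) -> np.random.Generator:
    """Return a Generator for stage ``names`` under ``master_seed``.

    The same (seed, names) pair always yields an identical stream; distinct
    name paths yield statistically independent streams.
    """
    keys = tuple(_name_key(n) for n in names)
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=keys)
    return np.random.default_rng(ss)


def child_seed(master_seed: int, *names: str) -> int:
    """A derived integer seed (< 2**31) for APIs that take a plain seed."""
    keys = tuple(_name_key(n) for n in names)
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=keys)
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
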