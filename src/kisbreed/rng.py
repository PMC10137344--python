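"""Named, reproducible random substreams.

All stochastic steps in kisbreed draw from substreams derived from one master
seed plus a sequence of names/indices (e.g. ``("founders",)`` or
``("meiosis", replicate, "F1")``).  Two substreams with different key paths
are statistically independent; the same key path always reproduces the same
stream.  This is what makes common-random-number comparisons across selection
methods possible: base-population and mating streams are keyed by replicate
and generation only, never by method.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _key_ints(master_seed: int, keys) -> list[int]:
    ints = [int(master_seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode("utf-8")))
        else:
            ints.append(int(k) & 0xFFFFFFFF)
    return ints


def substream(master_seed: int, *keys) -> np.random.Generator:
    """Return a Generator for the substream named by ``keys``."""
    return np.random.default_rng(np.random.SeedSequence(_key_ints(master_seed, keys)))


def child_seed(master_seed: int, *keys) -> int:
    """Derive a plain integer seed (< 2**31) for APIs that take one."""
    return int(substream(master_seed, *keys).integers(2**31))
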