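"""Hierarchical seed derivation.

Every stochastic operation takes one integer seed and derives a child
generator from ``(seed, tag)`` so that sub-steps are independent yet fully
reproducible, and so that re-ordering unrelated sub-steps never silently
changes a stream.
"""

from __future__ import annotations

import logging
import zlib

import numpy as np

logger = logging.getLogger("qtlcoloc")


def derive_rng(seed: int, *tags: object) -> np.random.Generator:
    """Return a Generator deterministically derived from ``seed`` and tags.

    Tags are hashed with CRC32 so string labels and small integers both work
    and the derivation is stable across platforms and Python hash seeds.
    """
    key = [int(seed) & 0x7FFFFFFF]
    for t in tags:
        key.append(zlib.crc32(str(t).encode("utf8")))
    ss = np.random.SeedSequence(key)
    logger.debug("derived rng seed=%s tags=%s", seed, tags)
    return np.random.default_rng(ss)


def derive_seed(seed: int, *tags: object) -> int:
    """A plain integer child seed (< 2**31) for APIs that want one."""
    ss = np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF] + [zlib.crc32(str(t).encode("utf8")) for t in tags]
    )
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
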