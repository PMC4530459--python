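"""Deterministic random-number substreams.

Every stochastic stage derives its generator from a single master seed plus a
tuple of string/int tags, so replaying any stage in isolation reproduces its
stream regardless of evaluation order.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31


def _tag_words(tags: tuple) -> list[int]:
    words = []
    for t in tags:
        if isinstance(t, (int, np.integer)):
            words.append(int(t) % _MOD)
        else:
            words.append(zlib.crc32(str(t).encode("utf-8")) % _MOD)
    return words


def substream(seed: int, *tags) -> np.random.Generator:
    """Generator for the named substream of ``seed``."""
    ss = np.random.SeedSequence([int(seed) % _MOD] + _tag_words(tags))
    return np.random.Generator(np.random.PCG64(ss))


def child_seed(seed: int, *tags) -> int:
    """A derived integer seed (< 2**31) for the named substream."""
    return int(substream(seed, *tags).integers(0, _MOD))
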