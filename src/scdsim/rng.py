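"""Named substream scheme for reproducible randomness.

One master seed feeds every stage of the pipeline; each stage (and each
simulated individual) draws from its own substream so that regenerating one
stage, or growing a cohort, never perturbs the others.  Substreams are
derived by hashing the stream name into a ``SeedSequence`` alongside the
master seed, which is stable across platforms and process restarts.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream_seed", "substream", "spawn_children"]


def _key(token: str | int) -> int:
    if isinstance(token, int):
        return token & 0xFFFFFFFF
    return zlib.crc32(token.encode("utf-8"))


def substream_seed(seed: int, *tokens: str | int) -> np.random.SeedSequence:
    """SeedSequence for the named substream ``tokens`` of ``seed``."""
    return np.random.SeedSequence([int(seed)] + [_key(t) for t in tokens])


def substream(seed: int, *tokens: str | int) -> np.random.Generator:
    """Generator for the named substream ``tokens`` of ``seed``."""
    return np.random.default_rng(substream_seed(seed, *tokens))


def spawn_children(ss: np.random.SeedSequence, n: int) -> list[np.random.SeedSequence]:
    """First ``n`` children of ``ss``; growing ``n`` keeps earlier children."""
    return np.random.SeedSequence(
        entropy=ss.entropy, spawn_key=ss.spawn_key
    ).spawn(n)
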