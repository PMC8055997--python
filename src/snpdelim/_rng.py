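"""Seed fan-out helpers.

One top-level integer seed governs every stochastic stage. Named
sub-streams are derived with :class:`numpy.random.SeedSequence` so that
stages are statistically independent and adding a stage (or a locus) never
shifts the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "stream_seed"]


def _key(name: str) -> int:
    # stable across runs and platforms, unlike hash()
    return zlib.crc32(name.encode("utf-8"))


def substream(seed: int, name: str, index: int | None = None) -> np.random.Generator:
    """Return a Generator for the named sub-stream of ``seed``.

    ``index`` addresses counter-based per-item streams (e.g. per locus):
    item *i* always receives the same draws regardless of how many other
    items exist.
    """
    if index is None:
        ss = np.random.SeedSequence(seed, spawn_key=(_key(name),))
    else:
        ss = np.random.SeedSequence(seed, spawn_key=(_key(name), int(index)))
    return np.random.default_rng(ss)


def stream_seed(seed: int, name: str, index: int | None = None) -> int:
    """A plain integer seed (< 2**31) for APIs that take one."""
    return int(substream(seed, name, index).integers(0, 2**31 - 1))
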