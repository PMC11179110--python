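"""Seed derivation: one user-facing integer seed, independent per-component streams."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _label_key(label: object) -> int:
    return zlib.crc32(str(label).encode())


def substream(seed: int, *labels: object) -> np.random.Generator:
    """Return a Generator for the stream named by ``labels`` under ``seed``.

    Distinct label tuples give statistically independent streams; the same
    tuple always gives the same stream.
    """
    key = [int(seed)] + [_label_key(l) for l in labels]
    return np.random.default_rng(np.random.SeedSequence(key))


def child_seed(seed: int, *labels: object) -> int:
    """A derived integer seed (< 2**31) for APIs that want a plain int."""
    return int(substream(seed, *labels).integers(2**31))
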