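"""Deterministic derivation of per-operation random substreams.

A single top-level seed is combined with a short string label so that every
stage of a run (simulation, permutation, bootstrap, ...) draws from its own
independent stream, and adding a stage never perturbs the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator for ``label`` derived from the top-level ``seed``.

    The label is hashed with CRC-32 and fed to a SeedSequence alongside the
    seed, so identical (seed, label) pairs give bit-identical streams on any
    platform.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    tag = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))
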