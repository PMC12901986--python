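"""Deterministic random-stream management.

Every stochastic operation takes an integer seed and derives an isolated
numpy Generator from it. Pipeline stages derive named substreams from the
single global seed so that enabling/disabling one stage never perturbs the
draws of another.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["rng_from_seed", "stage_rng"]


def rng_from_seed(seed: int) -> np.random.Generator:
    """Return a fresh PCG64 generator for an integer seed."""
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    return np.random.default_rng(int(seed))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Generator for a named substream of a global seed.

    The stage name is hashed (sha256) into the seed sequence entropy, so
    substreams are stable across runs and independent across stages.
    """
    digest = hashlib.sha256(stage.encode("utf-8")).digest()
    key = int.from_bytes(digest[:8], "big")
    ss = np.random.SeedSequence(entropy=[int(seed), key])
    return np.random.default_rng(ss)
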