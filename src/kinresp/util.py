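"""Shared plumbing: deterministic rounding and reproducible RNG splitting.

All stochastic stages take an explicit seed (or ``numpy.random.Generator``);
ensembles derive per-member child generators through ``spawn_rngs`` so that
any single member can be reproduced from the root seed alone.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["round_half_away", "as_rng", "spawn_rngs"]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero.

    Centralized so that tie cases (e.g. coupling 0.5 * 63 = 31.5 reactions)
    are deterministic across the whole pipeline.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def as_rng(seed_or_rng) -> np.random.Generator:
    """Coerce an int seed or an existing Generator into a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent child generators from one root seed.

    Uses ``numpy.random.SeedSequence.spawn`` so child streams are
    statistically independent and reproducible given (seed, index).
    """
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]
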