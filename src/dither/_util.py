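"""Small shared helpers: RNG plumbing and validation."""

from __future__ import annotations

import numpy as np


def as_rng(seed) -> np.random.Generator:
    """Return a Generator from an int seed, a Generator, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seed(rng: np.random.Generator) -> int:
    """Draw a child seed below 2**31 from an existing generator."""
    return int(rng.integers(0, 2**31 - 1))


def check_probabilities(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return p
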