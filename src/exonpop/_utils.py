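"""Small shared numerics: seeded sub-streams and harmonic numbers."""

from __future__ import annotations

import numpy as np

# Fixed per-operation offsets so each stage can be re-run independently from
# one root seed without correlated streams.
STREAM_COHORT = 1
STREAM_DEPTHS = 2
STREAM_CORRUPT = 3
STREAM_SHARING_MC = 4
STREAM_BOOTSTRAP = 5
STREAM_PLAN = 6


def substream(seed: int, offset: int) -> np.random.Generator:
    """Return an independent generator for (root seed, operation offset)."""
    return np.random.default_rng(np.random.SeedSequence(int(seed) & 0x7FFFFFFF,
                                                        spawn_key=(int(offset),)))


def harmonic(n: int) -> float:
    """H_n = sum_{i=1}^{n} 1/i (H_0 = 0)."""
    if n < 0:
        raise ValueError("harmonic number requires n >= 0")
    return float(np.sum(1.0 / np.arange(1, n + 1)))
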