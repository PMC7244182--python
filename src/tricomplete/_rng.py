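"""Seeded random-number generation helpers.

Every stochastic operation in the package takes an explicit integer seed and
builds its generator here, so runs are reproducible bit-for-bit. Philox is
counter-based, so independent streams derived from distinct seeds never
overlap.
"""

from __future__ import annotations

import numpy as np

_MOD = 2**31


def rng_from_seed(seed: int) -> np.random.Generator:
    """Return a counter-based generator for the given integer seed."""
    return np.random.Generator(np.random.Philox(key=int(seed)))


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive `n` reproducible child seeds (each < 2**31) from one seed."""
    rng = rng_from_seed(seed)
    return [int(s) for s in rng.integers(0, _MOD, size=n)]
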