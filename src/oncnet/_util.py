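"""Small shared helpers: deterministic allocation and rounding."""

from __future__ import annotations

import numpy as np


def largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Allocate `total` integer units proportionally to `fractions`.

    Standard largest-remainder (Hamilton) apportionment: floor the quotas,
    then hand the leftover units to the largest fractional remainders.
    Ties broken by position (first listed wins), which keeps the
    allocation deterministic.
    """
    fractions = np.asarray(fractions, dtype=float)
    if total < 0:
        raise ValueError("total must be nonnegative")
    if fractions.sum() <= 0:
        raise ValueError("fractions must have positive sum")
    quotas = fractions / fractions.sum() * total
    base = np.floor(quotas).astype(int)
    short = total - int(base.sum())
    if short > 0:
        remainders = quotas - base
        # stable sort so earlier categories win exact ties
        order = np.argsort(-remainders, kind="stable")
        base[order[:short]] += 1
    return base


def stochastic_round(x: float, rng: np.random.Generator) -> int:
    """Round to an integer with expectation x (floor + Bernoulli on the
    fractional part); negative inputs clip to 0."""
    if x <= 0:
        return 0
    lo = int(np.floor(x))
    frac = x - lo
    return lo + int(rng.random() < frac)


def spawn_rng(seed: int, *stream: int) -> np.random.Generator:
    """Independent child generator for a named stream of a master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))
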