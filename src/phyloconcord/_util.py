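"""Small shared helpers: rounding conventions and seeded RNG streams."""

from __future__ import annotations

import zlib
from decimal import Decimal, ROUND_HALF_UP

import numpy as np


def round_half_away(value: float, decimals: int = 0) -> float:
    """Round with halves going away from zero (not banker's rounding).

    All displayed percentages in this package use this convention:
    12/13 -> 92 (%), 130/350 -> 37.1 (%).
    """
    q = Decimal(1).scaleb(-decimals)
    d = Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage with the package-wide rounding rule; 0/0 -> 0.0."""
    if denominator == 0:
        return 0.0
    return round_half_away(100.0 * numerator / denominator, decimals)


def stream(seed: int, operation: str) -> np.random.Generator:
    """Independent RNG stream for one named operation.

    Streams are keyed by (seed, crc32(operation)) so adding new operations
    never perturbs the draws of existing ones.
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(operation.encode())])
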