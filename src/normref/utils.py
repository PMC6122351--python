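"""Small shared helpers."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

__all__ = ["round_half_up_percent", "log2_ratio"]


def log2_ratio(numerator, denominator):
    """log2(numerator / denominator) in a sign-canonical form.

    Computed as sign(num - den) * log2(max/min), which makes swapping the
    arguments an *exact* floating-point negation (antisymmetry holds
    bitwise) while preserving exact values for power-of-two ratios.
    0/0 yields NaN, x/0 yields +/- inf.
    """
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    hi = np.maximum(num, den)
    lo = np.minimum(num, den)
    with np.errstate(divide="ignore", invalid="ignore"):
        magnitude = np.log2(hi / lo)
        result = np.sign(num - den) * magnitude
    # equal and positive -> exactly 0 (sign is 0); both zero -> NaN
    result = np.where((num == den) & (num > 0), 0.0, result)
    if np.ndim(numerator) == 0 and np.ndim(denominator) == 0:
        return float(result)
    return result


def round_half_up_percent(count: int, denominator: int) -> int | None:
    """Integer percentage of ``count / denominator``, rounding halves up.

    Computed on the exact rational so 0.5 boundaries never suffer float
    error.  Returns ``None`` for a zero denominator (percentage undefined).
    """
    if denominator == 0:
        return None
    if count < 0 or denominator < 0:
        raise ValueError("count and denominator must be nonnegative")
    return int(math.floor(Fraction(100 * count, denominator) + Fraction(1, 2)))
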