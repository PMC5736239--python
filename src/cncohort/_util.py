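"""Shared numeric helpers.

All rounding in the package is *half away from zero* so that gains and
losses are treated symmetrically around a sample's ploidy.  Exact integer
(or rational) arithmetic is used wherever a .5 can occur, because binary
floating point cannot represent most rational window means exactly.
"""
from __future__ import annotations

from fractions import Fraction
from numbers import Rational


def round_half_away(x) -> int:
    """Round ``x`` to the nearest integer, halves away from zero.

    Accepts ints, Fractions and floats (floats are converted exactly).
    """
    if isinstance(x, int):
        return x
    f = x if isinstance(x, Rational) else Fraction(x)
    n, d = f.numerator, f.denominator
    if n >= 0:
        return (2 * n + d) // (2 * d)
    return -((-2 * n + d) // (2 * d))


def round_ratio_half_away(num: int, den: int) -> int:
    """Round the exact ratio num/den (den > 0) half away from zero."""
    if den <= 0:
        raise ValueError("denominator must be positive")
    if num >= 0:
        return (2 * num + den) // (2 * den)
    return -((-2 * num + den) // (2 * den))


def as_fraction(x) -> Fraction:
    """Coerce a ploidy-like value to an exact Fraction."""
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    if isinstance(x, float):
        # ploidies come from tie-averaging integers, so limit_denominator
        # recovers the intended rational (e.g. 2.5, 7/3) from the float
        return Fraction(x).limit_denominator(10**6)
    return Fraction(x)


def fmt_number(x) -> str:
    """Stable text rendering for matrix/ploidy values (no trailing zeros)."""
    f = as_fraction(x)
    if f.denominator == 1:
        return str(f.numerator)
    return repr(float(f))
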