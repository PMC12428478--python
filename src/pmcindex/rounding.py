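"""Half-up decimal rounding used everywhere a score is displayed.

All internal arithmetic is exact (``fractions.Fraction``); rounding happens
once, at display/classification time. Python's builtin ``round`` is
banker's rounding, which would turn 0.125 into 0.12; printed policy tables
use half-up (0.125 -> 0.13), so we go through ``decimal`` explicitly.
"""

from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from numbers import Rational


def round_half_up(value: Rational | float, ndigits: int = 2) -> float:
    """Round ``value`` half-up to ``ndigits`` decimal places, exactly.

    Rationals are converted to Decimal without a float detour so that e.g.
    ``Fraction(23, 3)`` rounds to 7.67 and ``Fraction(1, 3)`` to 0.33.
    """
    if isinstance(value, Rational):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(repr(float(value)))
    quantum = Decimal(1).scaleb(-ndigits)
    return float(dec.quantize(quantum, rounding=ROUND_HALF_UP))


def display(value: Rational | float, ndigits: int = 2) -> str:
    """Fixed-width string form of a rounded score (e.g. '7.67', '0.33')."""
    return f"{round_half_up(value, ndigits):.{ndigits}f}"


__all__ = ["round_half_up", "display", "Fraction"]
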