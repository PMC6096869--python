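"""Display-rounding policy.

All arithmetic in the package is carried out at full floating precision;
rounding happens only when a raw value is turned into its display form.
The policy is half-up (0.5 always rounds away from zero for the positive
quantities handled here), which is what the reference scenario tables use
— e.g. a duration of 161.54 days displays as 162 and 1038.46 as 1038, and
a cost of 15,112.50 displays as 15,113.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round ``value`` to ``ndigits`` decimal places, halves away from zero.

    Python's built-in ``round`` uses banker's rounding (15112.5 -> 15112),
    which does not match the display convention used here.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def display_money(value: float) -> int:
    """Money displays as whole currency units."""
    return int(round_half_up(value, 0))


def display_days(value: float) -> int:
    """Durations display as whole days."""
    return int(round_half_up(value, 0))


def display_percent(fraction: float) -> int:
    """A probability in [0, 1] displays as the nearest whole percent."""
    return int(round_half_up(fraction * 100.0, 0))


def display_utility(value: float) -> float:
    """Utility weights display to two decimal places."""
    return round_half_up(value, 2)
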