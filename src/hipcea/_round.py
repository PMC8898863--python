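"""Half-up rounding helpers for report-time rendering."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round ``value`` to ``ndigits`` decimal places, ties away from zero-up."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def round_pounds(value: float) -> int:
    """Whole-pound rendering: half-up to the nearest integer GBP."""
    return int(round_half_up(value, 0))
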