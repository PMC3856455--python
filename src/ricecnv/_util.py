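"""Shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round with ties going away from zero at the given decimal place.

    Printed summary tables in this package use conventional half-up
    rounding; Python's built-in ``round`` (banker's rounding) flips
    edge cases like 0.5 -> 0.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))
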