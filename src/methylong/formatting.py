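"""Percentage formatting with the report's rounding rule."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, decimals: int) -> float:
    """Round half away from zero (ROUND_HALF_UP on |x|), e.g. 8.85 -> 8.9."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(numerator: float, denominator: float) -> float:
    """100*num/den, one decimal; two significant digits below 1%."""
    if denominator == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    pct = 100.0 * numerator / denominator
    if 0 < abs(pct) < 1:
        # two significant digits, e.g. 0.7138 -> 0.71
        d = Decimal(repr(pct))
        exp = d.adjusted()  # -1 for 0.7x, -2 for 0.07x ...
        q = Decimal(1).scaleb(exp - 1)
        return float(d.quantize(q, rounding=ROUND_HALF_UP))
    return round_half_away(pct, 1)
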