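"""Round-half-up arithmetic for report tables.

Python's built-in round() is banker's rounding; published tables round
half away from zero, so every printed percent and mean goes through here.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, decimals: int = 0) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent_of(count: float, total: float, decimals: int = 2) -> float:
    """count/total as a percentage, rounded half-up to `decimals` places."""
    if total == 0:
        raise ZeroDivisionError("percent_of: total is zero")
    return round_half_up(count / total * 100.0, decimals)
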