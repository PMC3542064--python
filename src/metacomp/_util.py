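"""Small shared numerics."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention of printed percentages.

    Python's built-in round() is banker's rounding; report tables in this
    field round 0.005 up, so 26.105 -> 26.11 and -0.005 -> -0.01.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
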