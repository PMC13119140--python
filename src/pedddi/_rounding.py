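"""Half-away-from-zero rounding for comparisons against printed tables."""

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round ``x`` to ``decimals`` places, ties away from zero.

    Internal computation is always at full float precision; this is only
    applied when matching published two-decimal values, where banker's
    rounding (Python's built-in ``round``) would disagree on ties.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
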