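"""Small shared helpers."""

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int) -> float:
    """Round ``x`` to ``ndigits`` decimals, halves away from zero.

    Ratios and means are reported at fixed decimal precision with the
    conventional half-up rule (0.02075 -> 0.0208 at 4 decimals), which
    differs from Python's built-in banker's rounding.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
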