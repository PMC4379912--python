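"""Small shared helpers."""

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` half-up to ``ndigits`` decimals (table-reporting convention).

    Python's builtin ``round`` is banker's rounding; reported ages and
    percentages use conventional half-up instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
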