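"""Half-away-from-zero rounding for published-table rendering."""

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(value: float, decimals: int = 2) -> float:
    """Round with ties away from zero (the convention of printed clinical tables),
    unlike Python's banker's rounding."""
    if value != value:  # NaN
        return value
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
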