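"""Small shared numerics helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (spreadsheet-style),
    operating on the shortest decimal representation of ``x`` so binary
    float artifacts do not flip the tie-break."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
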