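"""Small numeric helpers shared across modules."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` half away from zero to ``ndigits`` decimal places.

    Map distances and kb/cM ratios are reported at the precision used in
    classical linkage tables (two decimals for cM, integers for kb), with
    ties broken upward rather than to-even.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def fmt_cm(x: float) -> str:
    return f"{round_half_up(x, 2):.2f}"
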