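"""Half-up decimal rounding.

Google Trends publishes integer relative search volumes and the study's
tables print percentages rounded half-up, so every user-facing rounding in
this package goes through :func:`round_half_up` rather than Python's
banker's-rounding ``round``.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimal places, ties away from zero upward.

    Operates on the shortest decimal representation of ``x`` so that values
    like ``0.355`` round to ``0.36`` as they would by hand.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
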