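"""Display rounding helpers.

Two conventions coexist in analytical reporting: regression coefficients
are conventionally rounded half-to-even, while tabulated validation
statistics (%RSD, mean squares, F) are typically truncated toward zero.
Internal arithmetic is never rounded; these helpers are display-only.
"""

from decimal import ROUND_DOWN, ROUND_HALF_EVEN, Decimal

__all__ = ["round_half_even", "truncate"]


def _quantum(ndigits: int) -> Decimal:
    return Decimal(1).scaleb(-ndigits)


def round_half_even(x: float, ndigits: int = 2) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going to the even digit.

    Uses decimal arithmetic on the shortest repr of ``x`` so that values
    like 13.625 round to 13.62 (not 13.63) regardless of binary artifacts.
    """
    return float(Decimal(str(float(x))).quantize(_quantum(ndigits), rounding=ROUND_HALF_EVEN))


def truncate(x: float, ndigits: int = 2) -> float:
    """Truncate ``x`` toward zero at ``ndigits`` decimals (no rounding)."""
    return float(Decimal(str(float(x))).quantize(_quantum(ndigits), rounding=ROUND_DOWN))
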