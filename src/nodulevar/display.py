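"""Display rounding.

Summary statistics and modelled volumes are reported at 1 decimal place with
half-up ties (the convention of clinical tables), while all internal
computation keeps full precision.  Binary floats sit a hair below decimal
ties (115 * 1.15 -> 132.2499...97), so the value is first snapped to 8
decimal places half-even to absorb representation error, then rounded
half-up (away from zero for negatives) at the requested precision.
"""

from __future__ import annotations

from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal

__all__ = ["round_display"]


def round_display(x: float, ndigits: int = 1) -> float:
    """Round ``x`` for display: decimal half-up after absorbing float fuzz."""
    d = Decimal(repr(float(x)))
    d = d.quantize(Decimal(1).scaleb(-8), rounding=ROUND_HALF_EVEN)
    return float(d.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))
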