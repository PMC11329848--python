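"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round4(x: float) -> float:
    """Round half-up to 4 decimals (report convention; 0.34375 -> 0.3438)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.0001"), ROUND_HALF_UP))
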