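"""Round-half-up helpers matching how the source tables print percentages."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "pct"]


def round_half_up(x: float, digits: int = 0) -> float:
    """Round with ties away from zero, as the published tables do (not
    banker's rounding)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(fraction: float, digits: int = 0) -> float:
    """A fraction in [0, 1] as a percentage rounded half-up."""
    value = round_half_up(fraction * 100.0, digits)
    return int(value) if digits == 0 else value
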