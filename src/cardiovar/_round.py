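"""Half-up decimal rounding and display formatting for report output.

Report conventions: odds ratios print with one decimal; confidence-interval
bounds print with one decimal below 20 and as integers at or above 20;
percentages print with one decimal (and additionally as whole percent where
a summary figure calls for it). Floats are serialized at full precision
elsewhere; these helpers apply display rounding only.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "format_or", "format_ci_bound", "format_pct"]

# CI bounds below this print with one decimal, at/above as integers.
CI_INTEGER_CUTOFF = 20.0


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (school rounding), not banker's."""
    q = Decimal(1) if ndigits == 0 else Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_or(value: float) -> str:
    return f"{round_half_up(value, 1):.1f}"


def format_ci_bound(value: float) -> str:
    if value < CI_INTEGER_CUTOFF:
        return f"{round_half_up(value, 1):.1f}"
    return f"{round_half_up(value, 0):.0f}"


def format_pct(value: float, ndigits: int = 1) -> str:
    return f"{round_half_up(value, ndigits):.{ndigits}f}"
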