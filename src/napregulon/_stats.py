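"""Small numeric helpers shared across modules."""

from __future__ import annotations

import math

__all__ = ["round_half_away", "percentage"]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero (72 from 71.83, -2 from -1.5).

    Python's built-in ``round`` uses banker's rounding; reported percentages
    use the away-from-zero convention instead.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percentage(k: float, n: float) -> int:
    """Integer percentage of ``k`` out of ``n``, rounded half away from zero."""
    if n == 0:
        return 0
    return round_half_away(100.0 * k / n)
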