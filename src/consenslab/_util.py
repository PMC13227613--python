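"""Small shared helpers: rounding conventions and minute-grid arithmetic."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

MINUTE = pd.Timedelta(minutes=1)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero, as printed report tables do.

    Python's built-in ``round`` uses banker's rounding; report rendering
    needs 0.5 -> 1.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 0) -> float:
    """Percentage with half-up rounding; denominator must be nonzero."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)


def floor_minute(ts: pd.Timestamp) -> pd.Timestamp:
    """Left edge of the half-open [t, t+60s) minute containing ``ts``."""
    return pd.Timestamp(ts).floor("min")
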