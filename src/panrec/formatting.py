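"""Ratio-to-percent formatting used in cohort summary reports.

Percentages are truncated (not rounded) to two decimals and trailing zeros
are stripped down to a minimum of one decimal, so 63/73 prints "86.3",
68/73 prints "93.15", 154/192 prints "80.2", and 81/400 prints "20.25".
"""

from __future__ import annotations

from decimal import ROUND_DOWN, Decimal


def format_ratio_percent(numerator: int, denominator: int) -> str:
    """Format numerator/denominator as a percent string (no '%' sign)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    value = Decimal(numerator) * 100 / Decimal(denominator)
    two = value.quantize(Decimal("0.01"), rounding=ROUND_DOWN)
    text = str(two)
    if text.endswith("0"):
        text = text[:-1]
    return text


def ratio_percent(numerator: int, denominator: int) -> float:
    """The formatted percent as a float (e.g. 86.3 for 63/73)."""
    return float(format_ratio_percent(numerator, denominator))
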