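"""Small cohort-summary helpers (characteristics-table arithmetic)."""

from __future__ import annotations


def rounded_percent(part: float, whole: float) -> int:
    """``100 * part / whole`` rounded to the nearest whole percent."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    if part < 0:
        raise ValueError("part must be non-negative")
    return int(round(100.0 * part / whole))


def drinker_percent(n_nondrinkers: int, n_total: int) -> int:
    """Percentage of current drinkers given non-drinker and total counts."""
    if n_nondrinkers > n_total:
        raise ValueError("non-drinkers cannot exceed the total")
    return rounded_percent(n_total - n_nondrinkers, n_total)
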