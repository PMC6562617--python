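"""Small shared helpers: decimal rounding and chromosome ordering."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (half-up), unlike Python's banker's rounding.

    All reported sizes and frequencies in this package use half-up rounding so
    that printed values are reproducible regardless of float parity effects.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    rounded = Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP)
    return float(rounded)


def chrom_sort_key(chrom: str) -> tuple:
    """Order chromosome labels numerically where possible (1, 2, ... 10, X)."""
    label = chrom[3:] if chrom.lower().startswith("chr") else chrom
    try:
        return (0, int(label), "")
    except ValueError:
        return (1, 0, label)
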