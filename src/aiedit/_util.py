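"""Small shared helpers: strand arithmetic and printed-style rounding."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = ("A", "C", "G", "T")


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero, as percentages are printed.

    Banker's rounding (Python's built-in ``round``) would turn 15.45 into
    15.4; reported percentages use the away-from-zero convention instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Percentage rounded for display; denominator must be positive."""
    if denominator <= 0:
        raise ValueError("percentage denominator must be positive")
    return round_half_up(100.0 * numerator / denominator, ndigits)
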