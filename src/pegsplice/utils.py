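"""Small shared helpers: reverse complement, half-up rounding, percentages."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_up(x: float, digits: int = 2) -> float:
    """Round to ``digits`` decimals with ties going away from zero.

    Report tables round this way (e.g. 54.1973 -> 54.20), unlike Python's
    banker's rounding.
    """
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(part: float, whole: float, digits: int = 2) -> float:
    """``part`` as a percentage of ``whole``, rounded half-up to ``digits``."""
    if whole == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    return round_half_up(100.0 * part / whole, digits)
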