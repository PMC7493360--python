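"""Small shared helpers: symbol normalisation, pair ordering, report rounding."""
from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip a gene/protein symbol. No alias resolution."""
    return str(symbol).strip().upper()


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the pair in canonical (lexicographically sorted) order."""
    a, b = normalize_symbol(a), normalize_symbol(b)
    return (a, b) if a <= b else (b, a)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (report convention).

    Python's built-in ``round`` is banker's rounding; reports here follow the
    convention of printed percentages where 0.5 rounds up in magnitude.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 0) -> float:
    """``100 * numerator / denominator`` rounded half-away-from-zero."""
    return round_half_away(100.0 * numerator / denominator, ndigits)
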