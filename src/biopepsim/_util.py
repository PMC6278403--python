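"""Shared helpers: the reporting rounding rule and the residue alphabet."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

#: The 20 canonical one-letter amino-acid codes.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity / non-standard codes rejected by default, tolerated in permissive mode.
AMBIGUOUS_CODES = frozenset("BZXUO")


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round to ``ndigits`` decimals, halves away from zero.

    Python's builtin ``round`` uses banker's rounding; reports here follow
    the convention that 0.0005 -> 0.001 (and -0.0005 -> -0.001).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
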