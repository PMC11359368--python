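"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention of printed reports).

    Python's built-in ``round`` uses banker's rounding, which would print
    2.5% as 2%; breeding reports round half up.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def derive_seed(seed: int, salt: int) -> int:
    """Deterministically derive a sub-seed below 2**31 from a master seed."""
    return (seed * 1_000_003 + salt * 7919 + 17) % (2**31 - 1)
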