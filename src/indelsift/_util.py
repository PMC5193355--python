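"""Small shared helpers: rounding and chromosome ordering."""

from __future__ import annotations

import re
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from numbers import Rational


def round_half_away(value, ndigits: int = 0):
    """Round to ``ndigits`` decimals with ties going away from zero.

    Python's builtin ``round`` uses banker's rounding; printed tables in the
    genomics literature almost universally use half-away-from-zero, so summary
    columns are rounded with this helper to reproduce printed precision.
    Returns an ``int`` when ``ndigits == 0``, else a ``float``.
    """
    if isinstance(value, Rational) and not isinstance(value, int):
        # exact path for Fractions (means computed without float error)
        value = Decimal(value.numerator) / Decimal(value.denominator)
    elif not isinstance(value, Decimal):
        value = Decimal(str(value))
    exp = Decimal(1).scaleb(-ndigits)
    q = value.quantize(exp, rounding=ROUND_HALF_UP)
    return int(q) if ndigits == 0 else float(q)


def exact_mean(values) -> Fraction:
    """Arithmetic mean as an exact rational (inputs parsed via str)."""
    vals = [Fraction(Decimal(str(v))) for v in values]
    if not vals:
        raise ValueError("mean of empty sequence")
    return sum(vals, Fraction(0)) / len(vals)


_CHROM_RE = re.compile(r"^(chr)?(\d+|[A-Za-z]+)$")


def chrom_sort_key(chrom: str):
    """Natural ordering: numeric chromosomes first by value, then X, Y, MT, others."""
    m = _CHROM_RE.match(chrom)
    body = m.group(2) if m else chrom
    if body.isdigit():
        return (0, int(body), "")
    special = {"X": 0, "Y": 1, "MT": 2, "M": 2}
    if body.upper() in special:
        return (1, special[body.upper()], "")
    return (2, 0, chrom)
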