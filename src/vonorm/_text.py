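"""Shared text normalization helpers.

Label normalization is deliberately minimal: lowercase, collapse internal
whitespace, strip.  No stemming — stemming mismatches are a distinct error
class downstream and must not be hidden by the index.
"""

from __future__ import annotations

import re

_WS = re.compile(r"\s+")


def normalize_label(text: str) -> str:
    """Lowercase, collapse runs of whitespace to single spaces, strip."""
    return _WS.sub(" ", text).strip().lower()


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal rounding with ties away from zero (half-up).

    Python's built-in round() is banker's rounding; report tables use the
    conventional half-up at a fixed number of decimals.
    """
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
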