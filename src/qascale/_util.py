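"""Shared numeric and seeding helpers."""

from __future__ import annotations

import hashlib
import re
from decimal import Decimal, ROUND_HALF_UP

_WS = re.compile(r"\s+")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero at `ndigits` decimals (report convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """Percentage rounded half-up; 0/0 reports 0."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, ndigits)


def normalize_term(text: str) -> str:
    """Whitespace-collapse and case-fold (Latin) for exact-string lookup."""
    return _WS.sub(" ", text).strip().casefold()


def stable_seed(*parts: object) -> int:
    """Deterministic sub-seed (< 2**31) derived from arbitrary labels.

    Independent of PYTHONHASHSEED so mock runs are reproducible across
    processes and concurrency settings.
    """
    h = hashlib.sha256("\x1f".join(str(p) for p in parts).encode("utf-8"))
    return int.from_bytes(h.digest()[:4], "big") % (2**31)
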