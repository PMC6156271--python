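"""Small numeric helpers shared across modules."""

from __future__ import annotations

import hashlib
import math


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties going away from zero.

    Python's built-in ``round`` uses banker's rounding; printed table
    percentages follow the convention that .5 rounds up in magnitude.
    """
    if x >= 0:
        return int(math.floor(x + 0.5))
    return -int(math.floor(-x + 0.5))


def round_sigfig(x: float, ndigits: int = 2) -> float:
    """Round ``x`` to ``ndigits`` significant figures (half away from zero)."""
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    scale = 10.0 ** (exp - ndigits + 1)
    return round_half_away(x / scale) * scale


def largest_remainder(n: int, proportions) -> list[int]:
    """Apportion ``n`` items to categories by largest-remainder rounding.

    Guarantees the counts sum to ``n`` exactly and equal ``n * p`` whenever
    those products are integers, so small fixtures have exact composition.
    Ties in remainder are broken toward earlier categories.
    """
    quotas = [n * p for p in proportions]
    counts = [int(math.floor(q)) for q in quotas]
    short = n - sum(counts)
    remainders = sorted(
        range(len(quotas)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in remainders[:short]:
        counts[i] += 1
    return counts


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()
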