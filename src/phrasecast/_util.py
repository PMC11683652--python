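"""Small shared helpers."""

from __future__ import annotations

import math
import re

_TOKEN_RE = re.compile(r"[0-9a-z]+")


def round_half_up(x: float) -> int:
    """Round to the nearest integer, with ties going away from zero-point-five
    upward (``0.5 -> 1``), matching how the reported percentages and mean ages
    are printed.

    Python's built-in ``round`` uses banker's rounding, which would turn
    ``49.5`` into ``50`` but ``48.5`` into ``48``; that is not what we want.
    """
    return math.floor(x + 0.5)


def tokenize(text: str) -> list[str]:
    """Lowercase and split on non-alphanumeric characters.

    This is the single tokenization used everywhere: word-boundary matching
    for phrase variants without stemming surprises.
    """
    return _TOKEN_RE.findall(text.lower())


def percent_half_up(numerator: int, denominator: int) -> int:
    """Integer percentage with half-up rounding; 0 when the denominator is 0."""
    if denominator == 0:
        return 0
    return round_half_up(100.0 * numerator / denominator)
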