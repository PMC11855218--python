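"""Coordinate convention conversions.

Internally every span is 0-based half-open ``[start, end)``.  All
human-facing output (GFF3, JSON reports, printed positions) is 1-based
inclusive.  Conversions live here and nowhere else.
"""

from __future__ import annotations


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open span -> 1-based inclusive span."""
    if start0 < 0 or end0 < start0:
        raise ValueError(f"invalid 0-based span ({start0}, {end0})")
    return start0 + 1, end0


def to_zero_based(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive span -> 0-based half-open span."""
    if start1 < 1 or end1 < start1 - 1:
        raise ValueError(f"invalid 1-based span ({start1}, {end1})")
    return start1 - 1, end1
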