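"""Interval-union arithmetic used by coverage and coding-density code."""

from __future__ import annotations

from typing import Iterable


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted, disjoint list."""
    ivals = sorted((s, e) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivals:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def union_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def overlap_length(intervals: Iterable[tuple[int, int]], window: tuple[int, int]) -> int:
    """Total bases of ``intervals`` (not necessarily disjoint) inside ``window``.

    Each interval contributes its clipped length; overlapping intervals count
    multiply, matching base-counting over individual reads.
    """
    ws, we = window
    return sum(max(0, min(e, we) - max(s, ws)) for s, e in intervals)
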