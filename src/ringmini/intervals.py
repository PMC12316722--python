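"""Closed-interval utilities.

Intervals are 1-based inclusive ``(start, end)`` tuples internally, matching
SAM coordinates; BED-style files are converted at the I/O boundary
(:mod:`ringmini.pipeline`).
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or book-ended closed intervals into a sorted union."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[Interval] = []
    for s, e in ivs:
        if e < s:
            raise ValueError(f"interval end before start: ({s}, {e})")
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def union_length(intervals: Iterable[Interval]) -> int:
    """Total number of bases covered by the union of the intervals."""
    return sum(e - s + 1 for s, e in merge_intervals(intervals))


def overlap_bases(intervals: Sequence[Interval], start: int, end: int) -> int:
    """Bases of ``[start, end]`` covered by the union of ``intervals``."""
    if end < start:
        return 0
    total = 0
    for s, e in merge_intervals(intervals):
        lo, hi = max(s, start), min(e, end)
        if lo <= hi:
            total += hi - lo + 1
        if s > end:
            break
    return total


def contains(interval: Interval, pos: int) -> bool:
    return interval[0] <= pos <= interval[1]


def jaccard(a: Interval, b: Interval) -> float:
    """Jaccard index of two closed intervals."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
    union = (a[1] - a[0] + 1) + (b[1] - b[0] + 1) - inter
    return inter / union if union else 0.0
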