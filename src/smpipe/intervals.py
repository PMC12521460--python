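"""Half-open time-interval arithmetic.

All intervals in the package are ``[start, end)`` in seconds from session
start.  Sets of intervals are plain lists of ``(start, end)`` tuples; the
helpers here keep them sorted and disjoint.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence, Tuple

Interval = Tuple[float, float]


def merge_intervals(intervals: Iterable[Interval], gap: float = 0.0) -> List[Interval]:
    """Sort intervals and merge any pair closer than ``gap`` seconds.

    With ``gap=0`` abutting intervals ([0,5), [5,8)) merge; overlapping ones
    always do.  Returns a sorted, disjoint list.
    """
    ivs = sorted((float(s), float(e)) for s, e in intervals)
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty or inverted interval [{s}, {e})")
    merged: List[Interval] = []
    for s, e in ivs:
        if merged and s - merged[-1][1] <= gap:
            ps, pe = merged[-1]
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def union(a: Sequence[Interval], b: Sequence[Interval]) -> List[Interval]:
    return merge_intervals(list(a) + list(b))


def intersect(a: Sequence[Interval], b: Sequence[Interval]) -> List[Interval]:
    """Pairwise intersection of two disjoint sorted interval sets."""
    out: List[Interval] = []
    i = j = 0
    a = sorted(a)
    b = sorted(b)
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_length(intervals: Sequence[Interval]) -> float:
    return float(sum(e - s for s, e in merge_intervals(intervals))) if intervals else 0.0


def overlap_length(a: Interval, b: Interval) -> float:
    return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))


def subtract(a: Sequence[Interval], b: Sequence[Interval]) -> List[Interval]:
    """Set difference a \\ b for disjoint sorted interval sets."""
    out: List[Interval] = []
    b = sorted(b)
    for s, e in sorted(a):
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out
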