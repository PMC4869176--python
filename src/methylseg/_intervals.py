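"""Half-open interval arithmetic on plain (start, end) tuples.

All coordinates are 0-based, half-open. Inputs need not be sorted; outputs are
sorted and pairwise disjoint.
"""

from __future__ import annotations

from collections.abc import Iterable

Interval = tuple[int, int]


def merge(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort and merge overlapping or touching intervals."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    """Return the part of ``a`` not covered by ``b`` (both merged first)."""
    a = merge(a)
    b = merge(b)
    out: list[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def complement(intervals: Iterable[Interval], length: int) -> list[Interval]:
    return subtract([(0, length)], intervals)


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge(intervals))


def clip(intervals: Iterable[Interval], length: int) -> list[Interval]:
    """Truncate intervals to [0, length); drop those that fall outside."""
    out = []
    for s, e in intervals:
        s, e = max(0, s), min(length, e)
        if e > s:
            out.append((s, e))
    return out


def overlap_length(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))
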