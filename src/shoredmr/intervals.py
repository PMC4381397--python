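"""Half-open interval algebra on sorted (start, end) tuples.

All intervals are 0-based half-open; zero-length overlap (shared boundary)
is no overlap, but `merge_union(..., merge_abutting=True)` will coalesce
abutting intervals where a caller wants base-pair union semantics.
"""

from __future__ import annotations

Interval = tuple[int, int]


def merge_union(intervals: list[Interval], merge_abutting: bool = True) -> list[Interval]:
    """Union of intervals as a sorted disjoint list.

    With merge_abutting, [0,100) + [100,200) -> [0,200); otherwise abutting
    intervals stay separate (used when touching must be distinguished from
    overlapping).
    """
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and (s < out[-1][1] or (merge_abutting and s == out[-1][1])):
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def subtract(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Set difference a \\ b; both inputs may be unsorted/overlapping."""
    a = merge_union(a)
    b = merge_union(b)
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
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def total_bp(intervals: list[Interval]) -> int:
    return sum(e - s for s, e in merge_union(intervals))


def overlaps(a: Interval, b: Interval) -> bool:
    """Strictly positive overlap on half-open intervals."""
    return a[0] < b[1] and b[0] < a[1]


def gap_distance(a: Interval, b: Interval) -> int:
    """0 if overlapping, else gap between the closest ends."""
    if overlaps(a, b):
        return 0
    if a[1] <= b[0]:
        return b[0] - a[1]
    return a[0] - b[1]


def point_to_interval_distance(p: int, iv: Interval) -> int:
    """Distance from a point to the nearest base of a half-open interval."""
    s, e = iv
    if s <= p < e:
        return 0
    return s - p if p < s else p - (e - 1)
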