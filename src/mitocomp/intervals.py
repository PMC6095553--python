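"""Half-open interval arithmetic on linear coordinates.

All coordinates in this module are 0-based half-open ``(start, end)``
tuples with ``start < end``. Circular wrap-around is resolved by callers
(e.g. :mod:`mitocomp.repeat_finder`) before intervals reach these
helpers.
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def merge(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or touching intervals into a sorted disjoint set."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def union_length(intervals: Iterable[Interval]) -> int:
    """Total number of positions covered by the union of ``intervals``."""
    return sum(e - s for s, e in merge(intervals))


def complement(intervals: Iterable[Interval], length: int) -> list[Interval]:
    """Intervals of ``[0, length)`` not covered by ``intervals``."""
    out: list[Interval] = []
    pos = 0
    for s, e in merge(intervals):
        if s < 0 or e > length:
            raise ValueError(f"interval ({s}, {e}) outside [0, {length})")
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if pos < length:
        out.append((pos, length))
    return out


def contains(container: Sequence[Interval], iv: Interval) -> bool:
    """True iff ``iv`` lies wholly inside the (merged) union of ``container``."""
    s, e = iv
    for cs, ce in merge(container):
        if cs <= s and e <= ce:
            return True
    return False


def overlaps(container: Sequence[Interval], iv: Interval) -> bool:
    """True iff ``iv`` overlaps the union of ``container`` by ≥ 1 bp."""
    s, e = iv
    return any(s < ce and cs < e for cs, ce in merge(container))


def intersect_length(a: Iterable[Interval], b: Iterable[Interval]) -> int:
    """Length of the intersection of two interval unions."""
    ma, mb = merge(a), merge(b)
    i = j = 0
    total = 0
    while i < len(ma) and j < len(mb):
        s = max(ma[i][0], mb[j][0])
        e = min(ma[i][1], mb[j][1])
        if e > s:
            total += e - s
        if ma[i][1] < mb[j][1]:
            i += 1
        else:
            j += 1
    return total
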