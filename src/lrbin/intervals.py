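"""Half-open integer intervals on read coordinates.

Everything downstream of the alignment parsers works with 0-based,
half-open intervals ``[lo, hi)`` on the forward strand of a read.  An
:class:`IntervalSet` is the normalized form: sorted, disjoint, with
abutting intervals merged, so that set algebra and measure are
unambiguous.  These primitives carry the whole interval-union machinery,
so they are implemented here rather than delegated.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort intervals and merge any that overlap or abut.

    Empty intervals (``lo >= hi``) are dropped.
    """
    items = sorted((lo, hi) for lo, hi in intervals if hi > lo)
    merged: list[Interval] = []
    for lo, hi in items:
        if merged and lo <= merged[-1][1]:
            if hi > merged[-1][1]:
                merged[-1] = (merged[-1][0], hi)
        else:
            merged.append((lo, hi))
    return merged


class IntervalSet:
    """A sorted, disjoint set of half-open integer intervals.

    Supports union (``|``), intersection (``&``) and total measure.
    Instances are immutable; all operations return new sets.
    """

    __slots__ = ("_intervals",)

    def __init__(self, intervals: Iterable[Interval] = ()):
        self._intervals: tuple[Interval, ...] = tuple(merge_intervals(intervals))

    @property
    def intervals(self) -> tuple[Interval, ...]:
        return self._intervals

    @property
    def measure(self) -> int:
        """Total number of positions covered."""
        return sum(hi - lo for lo, hi in self._intervals)

    def __bool__(self) -> bool:
        return bool(self._intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self._intervals)

    def __len__(self) -> int:
        return len(self._intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._intervals == other._intervals

    def __hash__(self) -> int:
        return hash(self._intervals)

    def __repr__(self) -> str:
        body = ", ".join(f"[{lo},{hi})" for lo, hi in self._intervals)
        return f"IntervalSet({body})"

    def __or__(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(self._intervals + other._intervals)

    def __and__(self, other: "IntervalSet") -> "IntervalSet":
        out: list[Interval] = []
        a, b = self._intervals, other._intervals
        i = j = 0
        while i < len(a) and j < len(b):
            lo = max(a[i][0], b[j][0])
            hi = min(a[i][1], b[j][1])
            if lo < hi:
                out.append((lo, hi))
            if a[i][1] < b[j][1]:
                i += 1
            else:
                j += 1
        return IntervalSet(out)

    def contains_interval(self, lo: int, hi: int) -> bool:
        """True iff [lo, hi) is entirely covered by this set."""
        for a, b in self._intervals:
            if a <= lo and hi <= b:
                return True
        return False

    @classmethod
    def union_all(cls, sets: Sequence["IntervalSet"]) -> "IntervalSet":
        pieces: list[Interval] = []
        for s in sets:
            pieces.extend(s._intervals)
        return cls(pieces)


def overlap_length(a: Interval, b: Interval) -> int:
    """Length of the intersection of two single intervals."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))
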