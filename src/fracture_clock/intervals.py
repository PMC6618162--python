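"""Exact set algebra over unions of half-open age intervals.

Fracture ages are measured in hours since the fracturing event.  A
feasible age range is in general not a single interval: the absence of a
histological feature excludes the window in which that feature is
universally seen, leaving a union of an early and a late interval.  The
algebra therefore closes over finite unions of half-open intervals
``[lo, hi)``, with ``math.inf`` permitted only as an upper endpoint.

All :class:`AgeSet` instances are kept *normalized*: intervals sorted by
lower endpoint, pairwise disjoint, and touching intervals merged, so
that structural equality is set equality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence, Tuple

INF = math.inf


@dataclass(frozen=True)
class AgeInterval:
    """Half-open interval ``[lo, hi)`` of fracture ages, in hours."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo >= 0:
            raise ValueError(f"lower endpoint must be >= 0, got {self.lo}")
        if math.isinf(self.lo):
            raise ValueError("lower endpoint must be finite")
        if not self.lo < self.hi:
            raise ValueError(f"empty interval [{self.lo}, {self.hi})")

    def contains(self, t: float) -> bool:
        return self.lo <= t < self.hi

    @property
    def length(self) -> float:
        return self.hi - self.lo

    def __str__(self) -> str:
        hi = "inf" if math.isinf(self.hi) else f"{self.hi:g}"
        return f"[{self.lo:g}, {hi})"


class AgeSet:
    """A normalized disjoint union of :class:`AgeInterval`.

    The empty set represents an infeasible combination of observations.
    Construction normalizes arbitrary input intervals (sorting, merging
    overlapping or touching ones), so every public operation both
    consumes and produces normalized sets.
    """

    __slots__ = ("_intervals",)

    def __init__(self, intervals: Iterable[AgeInterval] = ()) -> None:
        self._intervals: Tuple[AgeInterval, ...] = self._normalize(intervals)

    @staticmethod
    def _normalize(intervals: Iterable[AgeInterval]) -> Tuple[AgeInterval, ...]:
        ivals = sorted(intervals, key=lambda iv: (iv.lo, iv.hi))
        merged: list[AgeInterval] = []
        for iv in ivals:
            if merged and iv.lo <= merged[-1].hi:
                last = merged[-1]
                if iv.hi > last.hi:
                    merged[-1] = AgeInterval(last.lo, iv.hi)
            else:
                merged.append(iv)
        return tuple(merged)

    # ---- constructors -------------------------------------------------
    @classmethod
    def from_pairs(cls, pairs: Iterable[Sequence[float]]) -> "AgeSet":
        return cls(AgeInterval(lo, hi) for lo, hi in pairs)

    @classmethod
    def empty(cls) -> "AgeSet":
        return cls()

    @classmethod
    def full(cls, hi: float = INF) -> "AgeSet":
        return cls((AgeInterval(0.0, hi),))

    # ---- inspection ---------------------------------------------------
    @property
    def intervals(self) -> Tuple[AgeInterval, ...]:
        return self._intervals

    @property
    def is_empty(self) -> bool:
        return not self._intervals

    def contains(self, t: float) -> bool:
        return any(iv.contains(t) for iv in self._intervals)

    def measure(self, horizon: Optional[float] = None) -> float:
        """Total length, optionally clipped to ``[0, horizon)``."""
        s = self if horizon is None else self.clip(horizon)
        return sum(iv.length for iv in s._intervals)

    def span(self) -> Optional[AgeInterval]:
        """Smallest single interval containing the set; None if empty."""
        if not self._intervals:
            return None
        return AgeInterval(self._intervals[0].lo, self._intervals[-1].hi)

    # ---- algebra ------------------------------------------------------
    def intersect(self, other: "AgeSet") -> "AgeSet":
        out: list[AgeInterval] = []
        a, b = self._intervals, other._intervals
        i = j = 0
        while i < len(a) and j < len(b):
            lo = max(a[i].lo, b[j].lo)
            hi = min(a[i].hi, b[j].hi)
            if lo < hi:
                out.append(AgeInterval(lo, hi))
            if a[i].hi <= b[j].hi:
                i += 1
            else:
                j += 1
        return AgeSet(out)

    def union(self, other: "AgeSet") -> "AgeSet":
        return AgeSet(self._intervals + other._intervals)

    def complement(self, horizon: float = 2208.0) -> "AgeSet":
        """Set complement within ``[0, horizon)``."""
        out: list[AgeInterval] = []
        cursor = 0.0
        for iv in self._intervals:
            if iv.lo >= horizon:
                break
            if cursor < iv.lo:
                out.append(AgeInterval(cursor, min(iv.lo, horizon)))
            cursor = max(cursor, iv.hi)
        if cursor < horizon:
            out.append(AgeInterval(cursor, horizon))
        return AgeSet(out)

    def clip(self, horizon: float) -> "AgeSet":
        return self.intersect(AgeSet.full(horizon))

    def issubset(self, other: "AgeSet") -> bool:
        return self.intersect(other) == self

    def isdisjoint(self, other: "AgeSet") -> bool:
        return self.intersect(other).is_empty

    # ---- dunder -------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AgeSet):
            return NotImplemented
        return self._intervals == other._intervals

    def __hash__(self) -> int:
        return hash(self._intervals)

    def __iter__(self) -> Iterator[AgeInterval]:
        return iter(self._intervals)

    def __len__(self) -> int:
        return len(self._intervals)

    def __bool__(self) -> bool:
        return bool(self._intervals)

    def __repr__(self) -> str:
        body = " ∪ ".join(str(iv) for iv in self._intervals) or "∅"
        return f"AgeSet({body})"
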