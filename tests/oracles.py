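"""Independent brute-force oracles used to cross-check the engine.

These deliberately avoid the package's interval algebra: sets are
represented as boolean membership arrays on an hourly grid plus an
unboundedness flag, and partitions are enumerated exhaustively.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Iterable, List, Sequence, Tuple

import numpy as np

GRID_HI = 2400  # beyond the 2208-h horizon so tails are visible

Pairs = Sequence[Tuple[float, float]]


def grid(pairs: Pairs) -> Tuple[np.ndarray, bool]:
    """Membership of integer hours 0..GRID_HI-1 plus an 'unbounded' flag."""
    arr = np.zeros(GRID_HI, dtype=bool)
    unbounded = False
    for lo, hi in pairs:
        if math.isinf(hi):
            unbounded = True
            arr[int(lo):] = True
        else:
            arr[int(lo):min(int(hi), GRID_HI)] = True
    return arr, unbounded


def grid_of_ageset(s) -> Tuple[np.ndarray, bool]:
    return grid([(iv.lo, iv.hi) for iv in s.intervals])


def intersect(a: Pairs, b: Pairs) -> Tuple[np.ndarray, bool]:
    ga, ua = grid(a)
    gb, ub = grid(b)
    return ga & gb, ua and ub


def complement(a: Pairs, horizon: int) -> Tuple[np.ndarray, bool]:
    ga, _ = grid(a)
    out = ~ga
    out[horizon:] = False
    return out, False


def span_bounds(a: Pairs) -> Tuple[float, float] | None:
    ga, ua = grid(a)
    idx = np.flatnonzero(ga)
    if not len(idx):
        return None
    lo = float(idx[0])
    hi = math.inf if ua else float(idx[-1] + 1)
    return lo, hi


def all_partitions(items: Sequence[int]):
    """Every set partition of ``items`` (exhaustive enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def min_consistent_k(feature_grids: List[Tuple[np.ndarray, bool]]) -> int:
    """Minimal number of groups with non-empty joint membership."""
    n = len(feature_grids)
    if n == 0:
        return 0
    best = n
    for part in all_partitions(list(range(n))):
        ok = True
        for g in part:
            acc = np.ones(GRID_HI, dtype=bool)
            unb = True
            for i in g:
                acc &= feature_grids[i][0]
                unb = unb and feature_grids[i][1]
            if not acc.any() and not unb:
                ok = False
                break
        if ok:
            best = min(best, len(part))
    return best
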