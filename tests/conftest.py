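from __future__ import annotations

import random

import pytest

from fracture_clock import (
    AgeSet,
    FractureCase,
    Observation,
    default_kb,
)
from fracture_clock.intervals import INF, AgeInterval


@pytest.fixture(scope="session")
def kb():
    return default_kb()


def make_case(features, fracture_id="case", **kwargs) -> FractureCase:
    """Build a case from (feature, state[, region]) tuples."""
    obs = []
    for item in features:
        feature, state = item[0], item[1]
        region = item[2] if len(item) > 2 else "unspecified"
        obs.append(Observation(feature=feature, state=state, region=region))
    return FractureCase(fracture_id=fracture_id, observations=obs, **kwargs)


def random_ageset(rng: random.Random, max_edge: int = 2208,
                  allow_inf: bool = True) -> AgeSet:
    """Random normalized AgeSet with integer edges (possibly empty)."""
    n_edges = rng.randrange(0, 8)
    edges = sorted(rng.sample(range(0, max_edge + 1), n_edges))
    pairs = [(lo, hi) for lo, hi in zip(edges[::2], edges[1::2]) if lo < hi]
    intervals = [AgeInterval(lo, hi) for lo, hi in pairs]
    if allow_inf and rng.random() < 0.3:
        start = rng.randrange(0, max_edge + 1)
        intervals.append(AgeInterval(start, INF))
    return AgeSet(intervals)
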