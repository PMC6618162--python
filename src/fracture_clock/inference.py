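"""Fracture-age inference from histological observations.

Semantics of the tabulated healing timeline, applied per fracture:

* a feature recorded **present** constrains the age to
  ``[t_first, t_last)``;
* a feature recorded **absent** means the fracture has either not
  reached, or has passed, the window in which the feature is seen in
  all fractures: ``[0, t_all_on) ∪ [t_all_off, ∞)``;
* **unknown** observations and advisory-grade features carry no hard
  constraint.

Constraints from all observations are intersected exactly over the
interval algebra.  An empty intersection is never returned silently: it
signals observations of more than one fracturing event (or a mobile
fracture site) and is resolved by :func:`partition_events`, which finds
the minimal number of internally consistent event groups.

A discrete posterior over the KB's age bins complements the hard
constraints, treating the tabulated prevalence categories as
``P(feature present | age bin)``.

Ante-/post-mortem assessment is rule-based: peripheral osteocyte loss
or (redefined) ante-mortem haemorrhage in any region indicates an
ante-mortem fracture; absence of both is reported as indeterminate,
never as positive evidence of a post-mortem fracture.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .intervals import INF, AgeInterval, AgeSet
from .knowledgebase import (
    FeatureTimeline,
    KnowledgeBase,
    PrevalenceCategory,
    TimeBin,
    UnknownFeatureError,
    default_kb,
)

CASE_SCHEMA = "case-schema v1"

#: Features whose presence implies reacting bone tissue; forbidden in the
#: fracture line of a cartilage-only (growth-plate) fracture.
BONE_FEATURES = frozenset({
    "osteocyte_loss", "osteoclasis", "mesenchymal_condensation",
    "woven_osteoid", "trabeculae_cartilage", "calcification",
    "fracture_union", "lamellar_bone", "restoration",
})


class InferenceError(Exception):
    """Base class for inference errors."""


class CartilageOnlyError(InferenceError):
    """Fractures through growth-plate cartilage alone cannot be aged."""


class NoConstraintError(InferenceError):
    """The case carries no constraint-grade observation."""


class CaseSchemaError(InferenceError):
    """A case file does not parse against the published schema."""


class ObservationState(str, Enum):
    present = "present"
    absent = "absent"
    unknown = "unknown"


class Region(str, Enum):
    fracture_line = "fracture_line"
    periosteal_away = "periosteal_away"
    medullary = "medullary"
    unspecified = "unspecified"


class SiteClass(str, Enum):
    diaphyseal = "diaphyseal"
    metaphyseal = "metaphyseal"
    rib = "rib"


class Observation(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    feature: str
    state: ObservationState
    region: Region = Region.unspecified
    note: str = ""


class FractureCase(BaseModel):
    """One fracture's observations plus anatomical context flags."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    fracture_id: str
    bone: str = ""
    site_class: SiteClass = SiteClass.diaphyseal
    mobile: bool = False
    refracture_through_callus: bool = False
    cartilage_only: bool = False
    observations: List[Observation] = []

    @model_validator(mode="after")
    def _check_invariants(self) -> "FractureCase":
        seen: set[tuple[str, Region]] = set()
        for obs in self.observations:
            key = (obs.feature, obs.region)
            if key in seen:
                raise ValueError(
                    f"duplicate observation of {obs.feature!r} in region "
                    f"{obs.region.value!r}")
            seen.add(key)
        if self.cartilage_only:
            for obs in self.observations:
                if (obs.state is ObservationState.present
                        and obs.region is Region.fracture_line
                        and obs.feature in BONE_FEATURES):
                    raise ValueError(
                        f"cartilage-only fracture cannot show bone feature "
                        f"{obs.feature!r} in the fracture line")
        return self


def load_case(path: "str | Path") -> FractureCase:
    """Load one case file (``case-schema v1``, YAML or JSON)."""
    path = Path(path)
    if not path.exists():
        raise CaseSchemaError(f"no such file: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, Mapping):
        raise CaseSchemaError(f"{path}: top level must be a mapping")
    try:
        return FractureCase.model_validate(dict(raw))
    except (ValidationError, ValueError) as exc:
        raise CaseSchemaError(f"{path}: {exc}") from exc


def save_case(case: FractureCase, path: "str | Path") -> None:
    Path(path).write_text(yaml.safe_dump(case_to_dict(case), sort_keys=False))


def case_to_dict(case: FractureCase) -> dict:
    return {
        "fracture_id": case.fracture_id,
        "bone": case.bone,
        "site_class": case.site_class.value,
        "mobile": case.mobile,
        "refracture_through_callus": case.refracture_through_callus,
        "cartilage_only": case.cartilage_only,
        "observations": [
            {"feature": o.feature, "state": o.state.value,
             "region": o.region.value}
            for o in case.observations
        ],
    }


# ---------------------------------------------------------------------------
# Hard constraints
# ---------------------------------------------------------------------------

def constraint_for(
    obs: Observation,
    tl: FeatureTimeline,
    context: SiteClass = SiteClass.diaphyseal,
) -> AgeSet:
    """Age constraint contributed by one observation of one feature.

    The timeline is resolved through any context override first (e.g.
    metaphyseal cortical osteoclasis appears at 24 h instead of 72 h).
    Advisory-grade timelines and unknown states return the full range.
    """
    if obs.state is ObservationState.unknown:
        return AgeSet.full()
    tl = tl.resolve(context.value)
    if tl.constraint_grade == "advisory":
        return AgeSet.full()
    if obs.state is ObservationState.present:
        return tl.present_constraint()
    return tl.absent_constraint()


def effective_observations(
    case: FractureCase, kb: KnowledgeBase
) -> List[Observation]:
    """Observations that carry hard-constraint weight for this case.

    Unknown states and advisory features are dropped.  At a mobile
    fracture site only the periosteal reaction away from the fracture
    line reliably reflects the fracture's age, so other regions are
    demoted to advisory.
    """
    out: List[Observation] = []
    for obs in case.observations:
        tl = kb.feature(obs.feature)  # raises UnknownFeatureError
        if obs.state is ObservationState.unknown:
            continue
        if tl.constraint_grade == "advisory":
            continue
        if case.mobile and obs.region is not Region.periosteal_away:
            continue
        out.append(obs)
    return out


def feasible_ages(case: FractureCase, kb: KnowledgeBase) -> AgeSet:
    """Intersection of all constraint-grade observation constraints.

    Returned clipped to ``[0, horizon)``.  An empty set signals
    observations inconsistent with a single fracturing event; callers
    should resolve it through :func:`partition_events`.
    """
    if case.cartilage_only:
        raise CartilageOnlyError(
            f"{case.fracture_id}: fractures through growth-plate cartilage "
            "do not show features of repair and cannot be aged")
    acc = AgeSet.full(kb.horizon_hours)
    for obs in effective_observations(case, kb):
        acc = acc.intersect(constraint_for(obs, kb.feature(obs.feature),
                                           case.site_class))
    return acc


def pairwise_conflicts(
    case: FractureCase, kb: KnowledgeBase
) -> List[Tuple[str, str]]:
    """Pairs of observed features whose individual constraints are disjoint."""
    obs = effective_observations(case, kb)
    sets = [(o.feature, constraint_for(o, kb.feature(o.feature),
                                       case.site_class)) for o in obs]
    out = []
    for (f1, s1), (f2, s2) in itertools.combinations(sets, 2):
        if s1.isdisjoint(s2):
            out.append(tuple(sorted((f1, f2))))
    return sorted(set(out))


# ---------------------------------------------------------------------------
# Posterior over age bins
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Posterior:
    """Discrete posterior over the KB's age bins."""

    bins: Tuple[TimeBin, ...]
    probabilities: np.ndarray
    credible_indices: Tuple[int, ...]
    credible_mass: float
    prior: str

    def credible_bins(self) -> Tuple[TimeBin, ...]:
        return tuple(self.bins[i] for i in self.credible_indices)

    def contains_in_credible(self, t: float) -> bool:
        return any(self.bins[i].contains(t) for i in self.credible_indices)


def _prior_weights(bins: Sequence[TimeBin], prior: str) -> np.ndarray:
    if prior == "uniform_bins":
        return np.ones(len(bins))
    if prior == "uniform_log_time":
        # +1 h regularizes the bin at age 0 on the log-time axis
        return np.array([np.log((b.hi + 1.0) / (b.lo + 1.0)) for b in bins])
    raise ValueError(f"unknown prior {prior!r}")


def posterior_age(
    case: FractureCase,
    kb: KnowledgeBase,
    prior: str = "uniform_bins",
    credible_mass: float = 0.95,
) -> Posterior:
    """Posterior over age bins from the tabulated prevalence profiles.

    The prevalence category of each feature in each bin (evaluated at
    the bin midpoint; the default KB's bins are the finest partition on
    which all profiles are constant) is mapped to ``p = P(present |
    bin)``; the likelihood multiplies ``p`` for present and ``1 - p``
    for absent observations.  Category probabilities are bounded away
    from 0 and 1, so the posterior is always proper.

    The credible set is the smallest set of bins reaching the requested
    posterior mass (default 95%), ties broken toward earlier bins.
    """
    if case.cartilage_only:
        raise CartilageOnlyError(case.fracture_id)
    obs = effective_observations(case, kb)
    if not obs:
        raise NoConstraintError(
            f"{case.fracture_id}: no constraint-grade observation to "
            "support a posterior")
    cp = kb.category_probabilities
    bins = tuple(kb.bins)
    log_lik = np.zeros(len(bins))
    for o in obs:
        tl = kb.feature(o.feature).resolve(case.site_class.value)
        for i, b in enumerate(bins):
            p = cp.of(tl.category_at(b.mid))
            log_lik[i] += np.log(p if o.state is ObservationState.present
                                 else 1.0 - p)
    w = _prior_weights(bins, prior)
    log_post = np.log(w) + log_lik
    log_post -= log_post.max()
    post = np.exp(log_post)
    post /= post.sum()

    order = np.argsort(-post, kind="stable")
    cum = 0.0
    chosen: list[int] = []
    for i in order:
        chosen.append(int(i))
        cum += float(post[i])
        if cum >= credible_mass:
            break
    return Posterior(
        bins=bins,
        probabilities=post,
        credible_indices=tuple(sorted(chosen)),
        credible_mass=cum,
        prior=prior,
    )


# ---------------------------------------------------------------------------
# Ante-mortem classification
# ---------------------------------------------------------------------------

def classify_antemortem(
    case: FractureCase, kb: Optional[KnowledgeBase] = None
) -> str:
    """``"antemortem"`` or ``"indeterminate"``.

    Ante-mortem iff an ante-mortem marker feature is present in *any*
    region: haemorrhage (redefined to include medullary or periosteal
    haemorrhage without cortical red cells) or peripheral osteocyte
    loss, which is never seen in post-mortem fractures.  Absence of
    both is never positive evidence of a post-mortem fracture.
    """
    kb = kb if kb is not None else default_kb()
    markers = {tl.feature_id for tl in kb.features if tl.antemortem_marker}
    for obs in case.observations:
        if obs.state is ObservationState.present and obs.feature in markers:
            return "antemortem"
    return "indeterminate"


# ---------------------------------------------------------------------------
# Multi-event partitioning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EventGroup:
    """One fracturing event: its features and joint feasible ages."""

    features: Tuple[str, ...]
    feasible: AgeSet


@dataclass(frozen=True)
class EventPartition:
    n_events: int
    groups: Tuple[EventGroup, ...]


def _partition_score(
    groups: Sequence[Sequence[int]],
    sets: Sequence[AgeSet],
    horizon: float,
) -> float:
    """Tie-break score: per-group span overlap with member constraints."""
    total = 0.0
    for g in groups:
        inter = sets[g[0]]
        for i in g[1:]:
            inter = inter.intersect(sets[i])
        sp = inter.span()
        if sp is None:
            return -INF
        span_set = AgeSet((sp,))
        for i in g:
            total += span_set.intersect(sets[i]).measure(horizon)
    return total


def _enumerate_partitions(
    n: int, k: int, consistent, cap: int = 20000
):
    """All partitions of range(n) into exactly k consistent groups.

    Recursive restricted-growth enumeration with consistency pruning;
    deterministic order.  Stops after ``cap`` partitions (pathological
    inputs only); the first partition found is always yielded.
    """
    found = 0
    groups: list[list[int]] = []

    def rec(i: int):
        nonlocal found
        if found >= cap:
            return
        if i == n:
            if len(groups) == k:
                found += 1
                yield [list(g) for g in groups]
            return
        remaining = n - i
        for g in groups:
            g.append(i)
            if consistent(g):
                yield from rec(i + 1)
            g.pop()
        if len(groups) < k and remaining >= k - len(groups):
            groups.append([i])
            yield from rec(i + 1)
            groups.pop()

    yield from rec(0)


def minimal_consistent_partition(
    sets: Sequence[AgeSet],
) -> List[List[int]]:
    """Split indices into the minimal number of consistent groups.

    A group is consistent when the intersection of its members'
    age sets is non-empty (consistency is monotone under taking
    subsets, so an exact subset-DP applies).  Among minimal partitions
    the tie-break maximizes the span-overlap score, then takes the
    lexicographically least canonical form.
    """
    n = len(sets)
    if n == 0:
        return []
    full = (1 << n) - 1

    inter_cache: Dict[int, AgeSet] = {0: AgeSet.full()}

    def inter_of(mask: int) -> AgeSet:
        got = inter_cache.get(mask)
        if got is None:
            low = mask & -mask
            i = low.bit_length() - 1
            rest = mask ^ low
            got = sets[i] if rest == 0 else inter_of(rest).intersect(sets[i])
            inter_cache[mask] = got
        return got

    if not inter_of(full).is_empty:
        k_min = 1
    else:
        # subset-sum DP: f[mask] = min #consistent groups covering mask
        f = [0] * (full + 1)
        for mask in range(1, full + 1):
            low = mask & -mask
            best = n + 1
            sub = mask
            while sub:
                if sub & low and not inter_of(sub).is_empty:
                    cand = f[mask ^ sub] + 1
                    if cand < best:
                        best = cand
                sub = (sub - 1) & mask
            f[mask] = best
        k_min = f[full]

    def consistent(group: Sequence[int]) -> bool:
        mask = 0
        for i in group:
            mask |= 1 << i
        return not inter_of(mask).is_empty

    best_partition: Optional[List[List[int]]] = None
    best_key: Optional[tuple] = None
    for part in _enumerate_partitions(n, k_min, consistent):
        score = _partition_score(part, sets, 2208.0)
        canon = tuple(sorted(tuple(sorted(g)) for g in part))
        key = (-score, canon)
        if best_key is None or key < best_key:
            best_key = key
            best_partition = part
    assert best_partition is not None
    return sorted((sorted(g) for g in best_partition), key=tuple)


def partition_events(case: FractureCase, kb: KnowledgeBase) -> EventPartition:
    """Minimal partition of present features into consistent events.

    A refracture line passing completely through existing callus
    indicates a second, later fracturing event and forces at least two
    groups even when the features are mutually consistent.  Groups are
    returned oldest event first; a forced second event with no
    distinguishing features of its own is reported as an unevidenced
    youngest group with the full age range.
    """
    present: Dict[str, AgeSet] = {}
    for obs in effective_observations(case, kb):
        if obs.state is ObservationState.present:
            tl = kb.feature(obs.feature)
            present.setdefault(
                obs.feature, constraint_for(obs, tl, case.site_class))
    ids = sorted(present)
    sets = [present[f] for f in ids]

    index_groups = minimal_consistent_partition(sets)

    forced_split = case.refracture_through_callus and len(index_groups) < 2
    if forced_split and len(ids) >= 2:
        best = None
        best_key = None
        for part in _enumerate_partitions(len(ids), 2, lambda g: True):
            score = _partition_score(part, sets, kb.horizon_hours)
            canon = tuple(sorted(tuple(sorted(g)) for g in part))
            key = (-score, canon)
            if best_key is None or key < best_key:
                best_key, best = key, part
        index_groups = sorted((sorted(g) for g in best), key=tuple)
        forced_split = False

    groups = []
    for g in index_groups:
        inter = sets[g[0]]
        for i in g[1:]:
            inter = inter.intersect(sets[i])
        groups.append(EventGroup(tuple(ids[i] for i in g), inter))
    # oldest event first: order by descending lower bound of the span
    groups.sort(key=lambda gr: (-(gr.feasible.span().lo
                                  if gr.feasible.span() else -1.0),
                                gr.features))
    if not groups:
        # no present features: a single event of unconstrained age
        groups.append(EventGroup((), AgeSet.full(kb.horizon_hours)))
    if forced_split:
        # refracture evidenced only by the callus-crossing line itself
        groups.append(EventGroup((), AgeSet.full(kb.horizon_hours)))
    return EventPartition(n_events=len(groups), groups=tuple(groups))


# ---------------------------------------------------------------------------
# Case-level comparison and the assembled estimate
# ---------------------------------------------------------------------------

DISTINGUISHABLE = "distinguishably_different"
INDISTINGUISHABLE = "indistinguishable"


def compare_fractures(
    cases: Sequence[FractureCase], kb: KnowledgeBase
):
    """Symmetric matrix of pairwise age distinguishability.

    A pair is distinguishably different iff its feasible age sets are
    disjoint.  Returns a pandas DataFrame indexed by fracture id.
    """
    import pandas as pd

    ids = [c.fracture_id for c in cases]
    sets = [feasible_ages(c, kb) for c in cases]
    n = len(cases)
    mat = [[INDISTINGUISHABLE] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if sets[i].isdisjoint(sets[j]):
                mat[i][j] = mat[j][i] = DISTINGUISHABLE
    return pd.DataFrame(mat, index=ids, columns=ids)


@dataclass(frozen=True)
class AgeEstimate:
    """The full inference result for one fracture."""

    fracture_id: str
    feasible: AgeSet
    reported_range: Optional[AgeInterval]
    posterior: Optional[Posterior]
    antemortem: str                      # antemortem | indeterminate
    ageable: str                         # ageable | not_ageable_cartilage_only | beyond_horizon
    n_events: int
    event_groups: Tuple[EventGroup, ...]
    conflicts: Tuple[Tuple[str, str], ...] = ()

    def to_dict(self) -> dict:
        def ival(iv: Optional[AgeInterval]):
            if iv is None:
                return None
            return {"lo_hours": iv.lo,
                    "hi_hours": None if iv.hi == INF else iv.hi}

        return {
            "fracture_id": self.fracture_id,
            "ageable": self.ageable,
            "antemortem": self.antemortem,
            "feasible_intervals": [ival(iv) for iv in self.feasible],
            "reported_range": ival(self.reported_range),
            "posterior": None if self.posterior is None else {
                "prior": self.posterior.prior,
                "bins": [[b.lo, b.hi] for b in self.posterior.bins],
                "probabilities": [float(p)
                                  for p in self.posterior.probabilities],
                "credible_indices": list(self.posterior.credible_indices),
                "credible_mass": self.posterior.credible_mass,
            },
            "n_events": self.n_events,
            "event_groups": [
                {"features": list(g.features),
                 "feasible_intervals": [ival(iv) for iv in g.feasible]}
                for g in self.event_groups
            ],
            "conflicts": [list(c) for c in self.conflicts],
        }


def estimate_age(
    case: FractureCase,
    kb: Optional[KnowledgeBase] = None,
    *,
    prior: str = "uniform_bins",
    want_posterior: bool = True,
    credible_mass: float = 0.95,
) -> AgeEstimate:
    """Run the full inference pipeline for one fracture."""
    kb = kb if kb is not None else default_kb()
    antemortem = classify_antemortem(case, kb)

    if case.cartilage_only:
        return AgeEstimate(
            fracture_id=case.fracture_id, feasible=AgeSet.empty(),
            reported_range=None, posterior=None, antemortem=antemortem,
            ageable="not_ageable_cartilage_only", n_events=1,
            event_groups=(), conflicts=())

    restoration_present = any(
        o.feature == "restoration" and o.state is ObservationState.present
        for o in effective_observations(case, kb))
    if restoration_present:
        part = partition_events(case, kb)
        return AgeEstimate(
            fracture_id=case.fracture_id, feasible=AgeSet.empty(),
            reported_range=None, posterior=None, antemortem=antemortem,
            ageable="beyond_horizon", n_events=part.n_events,
            event_groups=part.groups,
            conflicts=tuple(pairwise_conflicts(case, kb)))

    feasible = feasible_ages(case, kb)
    part = partition_events(case, kb)
    conflicts = tuple(pairwise_conflicts(case, kb))
    posterior = None
    if want_posterior:
        try:
            posterior = posterior_age(case, kb, prior=prior,
                                      credible_mass=credible_mass)
        except NoConstraintError:
            posterior = None
    return AgeEstimate(
        fracture_id=case.fracture_id,
        feasible=feasible,
        reported_range=feasible.span(),
        posterior=posterior,
        antemortem=antemortem,
        ageable="ageable",
        n_events=part.n_events,
        event_groups=part.groups,
        conflicts=conflicts,
    )
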