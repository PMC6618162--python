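"""Knowledge base of histological feature timelines for infant fractures.

Each of 14 canonical histological features of fracture repair (from
haemorrhage through restoration of normal bone structure) carries a set
of temporal landmarks, all in hours since fracture:

``t_first``
    earliest age at which the feature has been observed;
``t_all_on`` / ``t_all_off``
    the window in which the feature is seen in *all* fractures
    (either may be undefined);
``t_last``
    latest age at which the feature may still be seen
    (undefined means unbounded).

Landmarks drive hard-constraint inference; a coarser per-age prevalence
profile (categories *none / minority / majority / all*, mapped to
configurable probabilities) drives the discrete Bayesian posterior and
the simulator.  Days in the source material are stored as ``24 * d``
hours; "by A–B days" transitions encode universal onset conservatively
at the upper end ``B``, with the lower end ``A`` retained in the
prevalence profile.

KBs are serialized as versioned YAML (``kb-schema v1``); the shipped
default file reproduces :func:`default_kb` exactly.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Any, Dict, List, Literal, Mapping, Optional, Sequence, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .intervals import INF, AgeInterval, AgeSet

KB_SCHEMA = "kb-schema v1"
DEFAULT_HORIZON_HOURS = 92 * 24.0  # restoration of normal structure by 92 days

#: The 14 canonical histological features, in assessment order.
CANONICAL_FEATURES: Tuple[str, ...] = (
    "haemorrhage",
    "fibrin",
    "polymorph_infiltrate",
    "macrophage_infiltrate",
    "granulation_tissue",
    "osteocyte_loss",
    "osteoclasis",
    "mesenchymal_condensation",
    "woven_osteoid",
    "trabeculae_cartilage",
    "calcification",
    "fracture_union",
    "lamellar_bone",
    "restoration",
)


class KBError(Exception):
    """Base class for knowledge-base errors."""


class KBSchemaError(KBError):
    """The file does not parse against the published schema."""


class KBValidationError(KBError):
    """The file parses but violates a knowledge-base invariant."""

    def __init__(self, issues: Sequence["Issue"]):
        self.issues = list(issues)
        super().__init__("; ".join(str(i) for i in issues))


class UnknownFeatureError(KBError, KeyError):
    """A referenced feature id is not in the knowledge base."""


class PrevalenceCategory(str, Enum):
    """Coarse proportion of same-age fractures showing a feature."""

    none = "none"
    minority = "minority"
    majority = "majority"
    all = "all"


class CategoryProbabilities(BaseModel):
    """Probability assigned to each prevalence category.

    Values are bounded away from 0 and 1 so that no single observation
    can zero out the posterior (no zero-likelihood traps).
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    none: float = 0.02
    minority: float = 0.30
    majority: float = 0.80
    all: float = 0.98

    def of(self, category: PrevalenceCategory) -> float:
        return getattr(self, category.value)

    def clamped(self, eps: float = 0.0) -> "CategoryProbabilities":
        """Push probabilities to the {eps, 1-eps} extremes.

        Categories at or above 1/2 (majority, all) go to ``1 - eps``,
        the rest to ``eps``.  With ``eps=0`` sampling becomes the
        noiseless deterministic limit.
        """
        def push(p: float) -> float:
            return 1.0 - eps if p >= 0.5 else eps

        return CategoryProbabilities(
            none=push(self.none),
            minority=push(self.minority),
            majority=push(self.majority),
            all=push(self.all),
        )


class ProfilePoint(BaseModel):
    """Prevalence category holding from ``from_hours`` onwards."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    from_hours: float
    category: PrevalenceCategory

    @model_validator(mode="before")
    @classmethod
    def _coerce_pair(cls, value: Any) -> Any:
        if isinstance(value, (list, tuple)) and len(value) == 2:
            return {"from_hours": value[0], "category": value[1]}
        return value


class ContextOverride(BaseModel):
    """Replacement landmarks applying in a named anatomical context."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    t_first: Optional[float] = None
    t_all_on: Optional[float] = None
    t_all_off: Optional[float] = None
    t_last: Optional[float] = None


class FeatureTimeline(BaseModel):
    """Temporal landmarks and prevalence profile of one feature."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    feature_id: str
    t_first: float = 0.0
    t_all_on: Optional[float] = None
    t_all_off: Optional[float] = None
    t_last: Optional[float] = None  # None = unbounded
    constraint_grade: Literal["constraint", "advisory"] = "constraint"
    antemortem_marker: bool = False
    inferred_defaults: List[str] = Field(default_factory=list)
    prevalence_profile: Optional[List[ProfilePoint]] = None
    context_overrides: Dict[str, ContextOverride] = Field(default_factory=dict)

    # -- landmark accessors --------------------------------------------
    @property
    def t_last_eff(self) -> float:
        return INF if self.t_last is None else self.t_last

    def resolve(self, context: Optional[str]) -> "FeatureTimeline":
        """Apply the override for ``context``, if any."""
        if not context or context not in self.context_overrides:
            return self
        ov = self.context_overrides[context]
        patch = {k: v for k, v in ov.model_dump().items() if v is not None}
        if patch and self.prevalence_profile is not None:
            # an explicit profile describes the generic context only;
            # fall back to the landmark-derived profile when overridden
            patch["prevalence_profile"] = None
        return self.model_copy(update=patch)

    # -- constraint semantics ------------------------------------------
    def present_constraint(self) -> AgeSet:
        """Ages compatible with the feature being present."""
        return AgeSet((AgeInterval(self.t_first, self.t_last_eff),))

    def absent_constraint(self) -> AgeSet:
        """Ages compatible with the feature being genuinely absent.

        A fracture lacking the feature has either not reached, or has
        passed, the window of universal presence; landmarks that are
        undefined drop the corresponding branch.
        """
        parts: list[AgeInterval] = []
        if self.t_all_on is not None and self.t_all_on > 0:
            parts.append(AgeInterval(0.0, self.t_all_on))
        if self.t_all_off is not None:
            parts.append(AgeInterval(self.t_all_off, INF))
        if self.t_all_on is None and self.t_all_off is None:
            return AgeSet.full()
        return AgeSet(parts)

    # -- prevalence -----------------------------------------------------
    def category_at(self, t: float) -> PrevalenceCategory:
        """Prevalence category at age ``t`` hours.

        Uses the explicit profile when present, otherwise derives it
        from the landmarks: none before ``t_first``; minority in
        ``[t_first, t_all_on)``; all in ``[t_all_on, t_all_off)``;
        majority in ``[t_all_off, t_last)``; none after ``t_last``.
        """
        if self.prevalence_profile:
            cat = PrevalenceCategory.none
            for pt in self.prevalence_profile:
                if t >= pt.from_hours:
                    cat = pt.category
                else:
                    break
            return cat
        if t < self.t_first or t >= self.t_last_eff:
            return PrevalenceCategory.none
        if self.t_all_on is None:
            return PrevalenceCategory.minority
        if t < self.t_all_on:
            return PrevalenceCategory.minority
        if self.t_all_off is None or t < self.t_all_off:
            return PrevalenceCategory.all
        return PrevalenceCategory.majority


class TimeBin(BaseModel):
    """Half-open age bin ``[lo, hi)`` in hours."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    lo: float
    hi: float

    @model_validator(mode="before")
    @classmethod
    def _coerce_pair(cls, value: Any) -> Any:
        if isinstance(value, (list, tuple)) and len(value) == 2:
            return {"lo": value[0], "hi": value[1]}
        return value

    @property
    def mid(self) -> float:
        return 0.5 * (self.lo + self.hi)

    def contains(self, t: float) -> bool:
        return self.lo <= t < self.hi


class KnowledgeBase(BaseModel):
    """A versioned table of feature timelines over an age axis."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    version: str
    horizon_hours: float = DEFAULT_HORIZON_HOURS
    category_probabilities: CategoryProbabilities = Field(
        default_factory=CategoryProbabilities
    )
    bins: List[TimeBin] = Field(default_factory=list)
    features: List[FeatureTimeline] = Field(default_factory=list)

    def feature(self, feature_id: str) -> FeatureTimeline:
        for tl in self.features:
            if tl.feature_id == feature_id:
                return tl
        raise UnknownFeatureError(feature_id)

    @property
    def feature_ids(self) -> Tuple[str, ...]:
        return tuple(tl.feature_id for tl in self.features)

    def bin_index(self, t: float) -> int:
        for i, b in enumerate(self.bins):
            if b.contains(t):
                return i
        raise ValueError(f"age {t} h outside the binned axis")

    # -- canonical form -------------------------------------------------
    def canonical_dict(self) -> Dict[str, Any]:
        """Plain-python canonical form used for serialization/hashing."""
        return {
            "version": self.version,
            "horizon_hours": self.horizon_hours,
            "category_probabilities": {
                c.value: self.category_probabilities.of(c)
                for c in PrevalenceCategory
            },
            "bins": [[b.lo, b.hi] for b in self.bins],
            "features": [
                {
                    "feature_id": tl.feature_id,
                    "t_first": tl.t_first,
                    "t_all_on": tl.t_all_on,
                    "t_all_off": tl.t_all_off,
                    "t_last": tl.t_last,
                    "constraint_grade": tl.constraint_grade,
                    "antemortem_marker": tl.antemortem_marker,
                    "inferred_defaults": list(tl.inferred_defaults),
                    "prevalence_profile": (
                        None
                        if tl.prevalence_profile is None
                        else [
                            [pt.from_hours, pt.category.value]
                            for pt in tl.prevalence_profile
                        ]
                    ),
                    "context_overrides": {
                        ctx: {
                            k: v
                            for k, v in ov.model_dump().items()
                            if v is not None
                        }
                        for ctx, ov in sorted(tl.context_overrides.items())
                    },
                }
                for tl in self.features
            ],
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.canonical_dict(), sort_keys=False)

    def kb_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Issue:
    """One machine-readable validation finding."""

    code: str
    message: str
    feature_id: Optional[str] = None

    def __str__(self) -> str:
        where = f" [{self.feature_id}]" if self.feature_id else ""
        return f"{self.code}{where}: {self.message}"


def _ordering_issues(
    fid: str, t_first: float, t_all_on: Optional[float],
    t_all_off: Optional[float], t_last: Optional[float], code: str,
) -> List[Issue]:
    """Check t_first <= t_all_on <= t_all_off <= t_last where defined."""
    seq = [("t_first", t_first), ("t_all_on", t_all_on),
           ("t_all_off", t_all_off), ("t_last", t_last)]
    defined = [(name, v) for name, v in seq if v is not None]
    out = []
    for (n1, v1), (n2, v2) in zip(defined, defined[1:]):
        if v1 > v2:
            out.append(Issue(code, f"{n1}={v1} > {n2}={v2}", fid))
    return out


def validate_kb(kb: KnowledgeBase) -> List[Issue]:
    """Return all invariant violations; empty list means valid.

    Never raises: a structurally parseable KB always yields a report.
    """
    issues: List[Issue] = []

    if not kb.features:
        issues.append(Issue("empty-features", "knowledge base has no features"))

    seen: set[str] = set()
    for tl in kb.features:
        if tl.feature_id in seen:
            issues.append(Issue("duplicate-feature",
                                "feature id appears more than once",
                                tl.feature_id))
        seen.add(tl.feature_id)

        issues.extend(_ordering_issues(
            tl.feature_id, tl.t_first, tl.t_all_on, tl.t_all_off, tl.t_last,
            "landmark-order"))
        for ctx in sorted(tl.context_overrides):
            r = tl.resolve(ctx)
            issues.extend(_ordering_issues(
                f"{tl.feature_id}/{ctx}", r.t_first, r.t_all_on, r.t_all_off,
                r.t_last, "override-order"))
        for name, v in (("t_first", tl.t_first), ("t_all_on", tl.t_all_on),
                        ("t_all_off", tl.t_all_off), ("t_last", tl.t_last)):
            if v is not None and not math.isinf(v) and v > kb.horizon_hours:
                issues.append(Issue("landmark-beyond-horizon",
                                    f"{name}={v} exceeds horizon "
                                    f"{kb.horizon_hours}", tl.feature_id))
        if tl.prevalence_profile:
            froms = [pt.from_hours for pt in tl.prevalence_profile]
            if froms != sorted(froms):
                issues.append(Issue("profile-order",
                                    "prevalence profile not in time order",
                                    tl.feature_id))

    cp = kb.category_probabilities
    probs = [cp.none, cp.minority, cp.majority, cp.all]
    if not all(0.0 < p < 1.0 for p in probs):
        issues.append(Issue("category-probability-range",
                            "category probabilities must lie strictly in (0,1)"))
    if not (cp.none < cp.minority < cp.majority < cp.all):
        issues.append(Issue("category-probability-order",
                            "category probabilities must increase "
                            "none < minority < majority < all"))

    if kb.bins:
        if kb.bins[0].lo != 0.0:
            issues.append(Issue("bin-cover", "first bin must start at 0"))
        if kb.bins[-1].hi != kb.horizon_hours:
            issues.append(Issue("bin-cover",
                                "last bin must end at the horizon"))
        for a, b in zip(kb.bins, kb.bins[1:]):
            if b.lo < a.hi:
                issues.append(Issue("bin-overlap",
                                    f"bins [{a.lo},{a.hi}) and "
                                    f"[{b.lo},{b.hi}) overlap"))
            elif b.lo > a.hi:
                issues.append(Issue("bin-gap",
                                    f"gap between {a.hi} and {b.lo}"))
        for b in kb.bins:
            if not b.lo < b.hi:
                issues.append(Issue("bin-order", f"bin [{b.lo},{b.hi}) empty"))

    return issues


# ---------------------------------------------------------------------------
# Default knowledge base
# ---------------------------------------------------------------------------

def _h(days: float) -> float:
    return 24.0 * days


def default_kb() -> KnowledgeBase:
    """The shipped default encoding of infant fracture-healing timelines.

    Landmarks follow the transcription convention documented in
    ``docs/methods.md``; under-specified landmarks are flagged in
    ``inferred_defaults`` and can be overridden in a user KB file.
    """
    P = PrevalenceCategory
    features = [
        # Ante-mortem haemorrhage (redefined to include medullary or
        # periosteal haemorrhage with or without RBC in the cortical
        # fracture line).  Absence carries no age constraint — red cells
        # may be lost during tissue processing — so the profile never
        # exceeds 'majority': absence stays possible at every age.
        FeatureTimeline(
            feature_id="haemorrhage",
            t_first=0.0,
            antemortem_marker=True,
            prevalence_profile=[
                ProfilePoint(from_hours=0.0, category=P.majority),
                ProfilePoint(from_hours=336.0, category=P.minority),
            ],
            inferred_defaults=["prevalence_profile"],
        ),
        # Distinct fibrin strands: universal at 12 h, increasing over
        # 24 h, then disappearing as other processes dominate.
        FeatureTimeline(
            feature_id="fibrin",
            t_first=2.0,
            t_all_on=12.0,
            t_all_off=72.0,
            t_last=168.0,
            inferred_defaults=["t_first", "t_all_off", "t_last"],
        ),
        # Polymorph infiltrate: very noticeable at the periphery of
        # haemorrhage by 18 h; short-lived.
        FeatureTimeline(
            feature_id="polymorph_infiltrate",
            t_first=12.0,
            t_all_on=18.0,
            t_all_off=48.0,
            t_last=96.0,
            inferred_defaults=["t_first", "t_all_off", "t_last"],
        ),
        # Macrophage infiltrate: not a universal finding; adds little to
        # ageing, so advisory — never tightens hard constraints.
        FeatureTimeline(
            feature_id="macrophage_infiltrate",
            t_first=72.0,
            constraint_grade="advisory",
            inferred_defaults=["t_first"],
        ),
        # Granulation tissue: fibroblast ingrowth then capillaries.
        FeatureTimeline(
            feature_id="granulation_tissue",
            t_first=72.0,
            t_all_on=120.0,
            inferred_defaults=["t_first", "t_all_on"],
        ),
        # Osteocyte loss at fracture-edge bone from 1 h; an ante-mortem
        # marker (never seen in post-mortem fractures).
        FeatureTimeline(
            feature_id="osteocyte_loss",
            t_first=1.0,
            t_all_on=168.0,
            antemortem_marker=True,
            inferred_defaults=["t_all_on"],
        ),
        # Osteoclasis: consistent burst throughout the fracture on days
        # 3-7; in metaphyseal fractures cortical osteoclasis appears
        # much earlier (24-36 h).
        FeatureTimeline(
            feature_id="osteoclasis",
            t_first=72.0,
            t_all_on=72.0,
            t_all_off=168.0,
            context_overrides={
                "metaphyseal": ContextOverride(t_first=24.0, t_all_on=36.0),
            },
        ),
        # Mesenchymal condensation in medulla and periosteum.
        FeatureTimeline(
            feature_id="mesenchymal_condensation",
            t_first=72.0,
            t_all_on=120.0,
            inferred_defaults=["t_first", "t_all_on"],
        ),
        # Early woven osteoid: universal by 5 days, increasing to 14.
        FeatureTimeline(
            feature_id="woven_osteoid",
            t_first=96.0,
            t_all_on=120.0,
            t_all_off=2208.0,
            inferred_defaults=["t_first", "t_all_off"],
        ),
        # Distinct bony trabeculae and cartilage nodules: by 8-14 days,
        # increasing to 21 days.
        FeatureTimeline(
            feature_id="trabeculae_cartilage",
            t_first=192.0,
            t_all_on=336.0,
        ),
        # Calcification: most fractures between 15 and 21 days, all by
        # 22-28 days.  Universal onset encoded at the conservative upper
        # end (28 d); the 22-d lower end starts the "all" prevalence.
        FeatureTimeline(
            feature_id="calcification",
            t_first=360.0,
            t_all_on=672.0,
            prevalence_profile=[
                ProfilePoint(from_hours=0.0, category=P.none),
                ProfilePoint(from_hours=360.0, category=P.majority),
                ProfilePoint(from_hours=528.0, category=P.all),
            ],
        ),
        # Bridging periosteal bony/cartilaginous callus by 22-28 days.
        FeatureTimeline(
            feature_id="fracture_union",
            t_first=504.0,
            t_all_on=672.0,
            inferred_defaults=["t_first"],
        ),
        # Lamellar bone on woven bone or cartilage nodules: never before
        # 28 days, always by 36 days.
        FeatureTimeline(
            feature_id="lamellar_bone",
            t_first=672.0,
            t_all_on=864.0,
        ),
        # Return towards normal bone structure, clearly established by
        # 92 days; presence signals ageing beyond the table's horizon.
        FeatureTimeline(
            feature_id="restoration",
            t_first=2208.0,
            t_all_on=2208.0,
        ),
    ]

    edges = [0.0, 1.0, 2.0, 12.0, 18.0, 24.0, 36.0, 48.0, 72.0, 96.0, 120.0,
             168.0, 192.0, 336.0, 360.0, 504.0, 528.0, 672.0, 864.0, 2208.0]
    bins = [TimeBin(lo=a, hi=b) for a, b in zip(edges, edges[1:])]

    return KnowledgeBase(
        version="default-2017.1",
        horizon_hours=DEFAULT_HORIZON_HOURS,
        category_probabilities=CategoryProbabilities(),
        bins=bins,
        features=features,
    )


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------

def default_kb_path() -> Path:
    return Path(str(resources.files("fracture_clock") / "data" / "default_kb.yaml"))


def load_kb(path: "str | Path") -> KnowledgeBase:
    """Load and fully validate a KB file (YAML or JSON).

    Raises :class:`KBSchemaError` on schema violations (naming the
    offending field) and :class:`KBValidationError` listing invariant
    issues; returns a validated :class:`KnowledgeBase` otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise KBSchemaError(f"no such file: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, Mapping):
        raise KBSchemaError(f"{path}: top level must be a mapping")
    try:
        kb = KnowledgeBase.model_validate(dict(raw))
    except ValidationError as exc:
        raise KBSchemaError(f"{path}: {exc}") from exc
    issues = validate_kb(kb)
    if issues:
        raise KBValidationError(issues)
    return kb


def save_kb(kb: KnowledgeBase, path: "str | Path") -> None:
    Path(path).write_text(kb.to_yaml())
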