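"""Case-level report assembly.

A :class:`CaseReport` bundles the per-fracture age estimates, the
pairwise distinguishability matrix, caveat codes, and provenance (KB
version and hash, engine version, seed).  The JSON rendering is the
single source of truth; the human-readable text report is derived from
the JSON dictionary only, so both carry identical numbers.

Ages are printed in hours below 72 h and in days at or above, matching
the hour/day split of the source table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from . import __version__ as ENGINE_VERSION
from .inference import (
    AgeEstimate,
    FractureCase,
    compare_fractures,
    estimate_age,
)
from .knowledgebase import KnowledgeBase, default_kb

CAVEAT_TEXT: Dict[str, str] = {
    "MOBILE_SITE": ("mobile fracture site: only the periosteal reaction "
                    "away from the fracture line was used for ageing"),
    "METAPHYSEAL": ("metaphyseal fracture: cortical osteoclasis timings "
                    "use the earlier metaphyseal timeline"),
    "CARTILAGE_ONLY": ("fracture through growth-plate cartilage only: "
                       "shows no features of repair and cannot be aged"),
    "BEYOND_HORIZON": ("restoration towards normal structure present: "
                       "fracture older than the 92-day horizon, "
                       "differential ageing difficult"),
    "MULTIPLE_EVENTS": ("observations indicate more than one fracturing "
                        "event (refracture or mixed-age reactions)"),
    "CONFLICT": ("individually observed features have non-overlapping age "
                 "constraints; review for refracture or mobile site"),
}


def _case_caveats(case: FractureCase, est: AgeEstimate) -> List[str]:
    codes = []
    if case.mobile:
        codes.append("MOBILE_SITE")
    if case.site_class.value == "metaphyseal":
        codes.append("METAPHYSEAL")
    if est.ageable == "not_ageable_cartilage_only":
        codes.append("CARTILAGE_ONLY")
    if est.ageable == "beyond_horizon":
        codes.append("BEYOND_HORIZON")
    if est.n_events > 1 or case.refracture_through_callus:
        codes.append("MULTIPLE_EVENTS")
    if est.conflicts:
        codes.append("CONFLICT")
    return codes


@dataclass
class CaseReport:
    estimates: List[dict]
    comparison: Optional[dict]
    caveats: Dict[str, List[str]]
    kb_version: str
    kb_hash: str
    engine_version: str = ENGINE_VERSION
    seed: Optional[int] = None

    def to_json_dict(self) -> dict:
        return {
            "engine_version": self.engine_version,
            "kb_version": self.kb_version,
            "kb_hash": self.kb_hash,
            "seed": self.seed,
            "caveats": self.caveats,
            "caveat_text": {c: CAVEAT_TEXT[c]
                            for codes in self.caveats.values()
                            for c in codes},
            "estimates": self.estimates,
            "comparison": self.comparison,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), indent=2)

    def to_text(self) -> str:
        return render_text(self.to_json_dict())


def run_case(
    cases: Sequence[FractureCase],
    kb: Optional[KnowledgeBase] = None,
    *,
    want_posterior: bool = False,
    prior: str = "uniform_bins",
    credible_mass: float = 0.95,
    seed: Optional[int] = None,
) -> CaseReport:
    """Validate, infer, partition, compare and assemble the report."""
    kb = kb if kb is not None else default_kb()
    estimates = []
    caveats: Dict[str, List[str]] = {}
    by_id: Dict[str, AgeEstimate] = {}
    for case in cases:
        est = estimate_age(case, kb, prior=prior,
                           want_posterior=want_posterior,
                           credible_mass=credible_mass)
        by_id[case.fracture_id] = est
        estimates.append(est.to_dict())
        caveats[case.fracture_id] = _case_caveats(case, est)

    comparison = None
    ageable = [c for c in cases if by_id[c.fracture_id].ageable == "ageable"]
    if len(ageable) >= 2:
        df = compare_fractures(ageable, kb)
        comparison = {"ids": list(df.index),
                      "matrix": df.values.tolist()}

    return CaseReport(
        estimates=estimates,
        comparison=comparison,
        caveats=caveats,
        kb_version=kb.version,
        kb_hash=kb.kb_hash(),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Text rendering (from the JSON dict only)
# ---------------------------------------------------------------------------

def format_age(hours: Optional[float]) -> str:
    """Render an age in hours below 72 h, in days at or above."""
    if hours is None:
        return "open-ended"
    if hours < 72.0:
        return f"{hours:g} h"
    return f"{hours / 24.0:g} days"


def _format_interval(iv: Optional[dict]) -> str:
    if iv is None:
        return "none"
    lo = format_age(iv["lo_hours"])
    hi = "open-ended" if iv["hi_hours"] is None else format_age(iv["hi_hours"])
    return f"{lo} to {hi}"


def render_text(doc: dict) -> str:
    lines: List[str] = []
    lines.append(f"fracture-clock {doc['engine_version']} | "
                 f"KB {doc['kb_version']} ({doc['kb_hash'][:12]})")
    for est in doc["estimates"]:
        lines.append("")
        lines.append(f"Fracture {est['fracture_id']}: {est['ageable']}, "
                     f"{est['antemortem']}")
        if est["ageable"] == "ageable":
            lines.append(f"  age range: {_format_interval(est['reported_range'])}")
            for iv in est["feasible_intervals"]:
                lines.append(f"    feasible: {_format_interval(iv)}")
        if est["posterior"] is not None:
            post = est["posterior"]
            mass = post["credible_mass"]
            bins = [post["bins"][i] for i in post["credible_indices"]]
            if bins:
                lo, hi = bins[0][0], bins[-1][1]
                lines.append(f"  {mass:.0%} credible bins span "
                             f"{format_age(lo)} to {format_age(hi)} "
                             f"({len(bins)} bins, prior {post['prior']})")
        if est["n_events"] > 1:
            lines.append(f"  events detected: {est['n_events']}")
            for g in est["event_groups"]:
                feats = ", ".join(g["features"]) or "(no distinct features)"
                spans = "; ".join(_format_interval(iv)
                                  for iv in g["feasible_intervals"]) or "any"
                lines.append(f"    event [{feats}]: {spans}")
        for code in doc["caveats"].get(est["fracture_id"], []):
            lines.append(f"  caveat {code}: {CAVEAT_TEXT[code]}")
    if doc.get("comparison"):
        lines.append("")
        lines.append("Pairwise age comparison:")
        ids = doc["comparison"]["ids"]
        mat = doc["comparison"]["matrix"]
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                verdict = mat[i][j].replace("_", " ")
                lines.append(f"  {a} vs {ids[j]}: {verdict}")
    return "\n".join(lines) + "\n"
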