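"""Inference semantics: constraints, posterior, verdicts, partitioning."""

from __future__ import annotations

import random

import numpy as np
import pytest

from fracture_clock import (
    AgeSet,
    CartilageOnlyError,
    FractureCase,
    NoConstraintError,
    Observation,
    classify_antemortem,
    compare_fractures,
    constraint_for,
    estimate_age,
    feasible_ages,
    partition_events,
    posterior_age,
)
from fracture_clock.inference import (
    ObservationState,
    SiteClass,
    load_case,
    save_case,
)
from fracture_clock.intervals import INF
from fracture_clock.knowledgebase import PrevalenceCategory, UnknownFeatureError

from conftest import make_case
from oracles import grid, min_consistent_k

P, A, U = "present", "absent", "unknown"


def obs(feature, state, region="unspecified"):
    return Observation(feature=feature, state=state, region=region)


class TestConstraintFor:
    def test_present_bounds_by_first_and_last(self, kb):
        s = constraint_for(obs("lamellar_bone", P), kb.feature("lamellar_bone"))
        assert s == AgeSet.from_pairs([(672, INF)])

    def test_absent_excludes_universal_window(self, kb):
        s = constraint_for(obs("fibrin", A), kb.feature("fibrin"))
        assert s == AgeSet.from_pairs([(0, 12), (72, INF)])

    def test_absent_without_all_off_drops_late_branch(self, kb):
        s = constraint_for(obs("trabeculae_cartilage", A),
                           kb.feature("trabeculae_cartilage"))
        assert s == AgeSet.from_pairs([(0, 336)])

    def test_absent_with_no_universal_window_is_unconstrained(self, kb):
        s = constraint_for(obs("haemorrhage", A), kb.feature("haemorrhage"))
        assert s == AgeSet.full()

    def test_advisory_feature_never_constrains(self, kb):
        tl = kb.feature("macrophage_infiltrate")
        assert constraint_for(obs("macrophage_infiltrate", P), tl) \
            == AgeSet.full()
        assert constraint_for(obs("macrophage_infiltrate", A), tl) \
            == AgeSet.full()

    def test_unknown_state_carries_no_constraint(self, kb):
        assert constraint_for(obs("fibrin", U), kb.feature("fibrin")) \
            == AgeSet.full()

    def test_metaphyseal_context_shifts_osteoclasis(self, kb):
        tl = kb.feature("osteoclasis")
        dia = constraint_for(obs("osteoclasis", P), tl, SiteClass.diaphyseal)
        met = constraint_for(obs("osteoclasis", P), tl, SiteClass.metaphyseal)
        assert dia.span().lo == 72 and met.span().lo == 24


class TestFeasibleAges:
    def test_single_present_feature_clipped_to_horizon(self, kb):
        s = feasible_ages(make_case([("osteocyte_loss", P)]), kb)
        assert s == AgeSet.from_pairs([(1, kb.horizon_hours)])

    def test_no_observations_gives_full_horizon(self, kb):
        s = feasible_ages(make_case([]), kb)
        assert s == AgeSet.from_pairs([(0, kb.horizon_hours)])

    def test_incompatible_features_conflict(self, kb):
        s = feasible_ages(make_case([("fibrin", P), ("calcification", P)]), kb)
        assert s.is_empty

    def test_combined_presence_and_absence(self, kb):
        # woven osteoid present but no trabeculae yet: 4-14 days
        s = feasible_ages(make_case([("woven_osteoid", P),
                                     ("trabeculae_cartilage", A)]), kb)
        assert s == AgeSet.from_pairs([(96, 336)])

    def test_cartilage_only_cannot_be_aged(self, kb):
        case = make_case([], cartilage_only=True)
        with pytest.raises(CartilageOnlyError):
            feasible_ages(case, kb)

    def test_unknown_feature_id_rejected(self, kb):
        case = make_case([("made_up_feature", P)])
        with pytest.raises(UnknownFeatureError):
            feasible_ages(case, kb)

    def test_mobile_site_uses_periosteal_region_only(self, kb):
        case = make_case([
            ("calcification", P, "fracture_line"),   # mixed-age reaction
            ("fibrin", P, "periosteal_away"),
        ], mobile=True)
        # away-from-line periosteal reaction wins; line obs demoted
        assert feasible_ages(case, kb) == AgeSet.from_pairs([(2, 168)])

    def test_monotone_under_added_observations(self, kb):
        rng = random.Random(11)
        states = [P, A]
        for _ in range(100):
            feats = rng.sample(kb.feature_ids, rng.randrange(0, 6))
            items = [(f, rng.choice(states)) for f in feats]
            base = feasible_ages(make_case(items), kb)
            extra = rng.choice([f for f in kb.feature_ids
                                if f not in feats])
            bigger = feasible_ages(
                make_case(items + [(extra, rng.choice(states))]), kb)
            assert bigger.issubset(base)

    def test_noiseless_consistency_at_every_feasible_age(self, kb):
        # at any age, observing exactly the majority/all features present
        # must re-infer a set containing that age
        rng = random.Random(5)
        majority_up = {PrevalenceCategory.majority, PrevalenceCategory.all}
        for _ in range(200):
            age = rng.uniform(0, kb.horizon_hours)
            site = rng.choice(list(SiteClass))
            items = []
            for tl in kb.features:
                cat = tl.resolve(site.value).category_at(age)
                items.append((tl.feature_id,
                              P if cat in majority_up else A))
            s = feasible_ages(make_case(items, site_class=site), kb)
            assert s.contains(age), (age, site)


class TestPosterior:
    def test_normalized_for_random_cases(self, kb):
        rng = random.Random(3)
        for _ in range(50):
            feats = rng.sample(kb.feature_ids, rng.randrange(1, 6))
            items = [(f, rng.choice([P, A])) for f in feats]
            try:
                post = posterior_age(make_case(items), kb)
            except NoConstraintError:
                continue
            assert post.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
            assert (post.probabilities >= 0).all()

    def test_unknown_only_case_rejected(self, kb):
        case = make_case([("fibrin", U)])
        with pytest.raises(NoConstraintError):
            posterior_age(case, kb)

    def test_remodelling_case_concentrates_late(self, kb):
        # hand-computed 19-bin table: lamellar present has p=0.02 in the
        # 17 bins before 672 h, 0.30 in [672,864) and 0.98 in [864,2208);
        # restoration absent contributes a constant 0.98 per bin
        post = posterior_age(make_case([("lamellar_bone", P),
                                        ("restoration", A)]), kb)
        lik = np.array([0.02] * 17 + [0.30, 0.98]) * 0.98
        expected = lik / lik.sum()
        np.testing.assert_allclose(post.probabilities, expected, rtol=1e-12)
        assert expected[17] + expected[18] == pytest.approx(0.79, abs=0.005)
        top_two = np.argsort(post.probabilities)[-2:]
        assert {17, 18} == set(top_two)

    def test_log_time_prior_reweights_but_keeps_support(self, kb):
        case = make_case([("fibrin", P)])
        p1 = posterior_age(case, kb, prior="uniform_bins")
        p2 = posterior_age(case, kb, prior="uniform_log_time")
        assert p2.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        assert not np.allclose(p1.probabilities, p2.probabilities)

    def test_credible_set_is_smallest_mass_set(self, kb):
        post = posterior_age(make_case([("woven_osteoid", P)]), kb)
        mass = post.probabilities[list(post.credible_indices)].sum()
        assert mass >= 0.95
        # dropping the least-probable chosen bin falls below the mass
        drop = min(post.credible_indices,
                   key=lambda i: post.probabilities[i])
        rest = [i for i in post.credible_indices if i != drop]
        assert post.probabilities[rest].sum() < 0.95

    def test_credible_set_within_constraint_span_at_extreme_probs(self, kb):
        # posterior -> hard-constraint limit agreement: presence is
        # impossible only in 'none' bins and absence only in 'all' bins,
        # so the faithful limit map sends those to the extremes and the
        # two intermediate categories to 1/2
        doc = kb.model_dump()
        doc["category_probabilities"] = dict(
            none=1e-9, minority=0.5, majority=0.5, all=1 - 1e-9)
        from fracture_clock import KnowledgeBase
        kb_ext = KnowledgeBase.model_validate(doc)
        rng = random.Random(17)
        checked = 0
        while checked < 40:
            feats = rng.sample(kb.feature_ids, rng.randrange(1, 5))
            items = [(f, rng.choice([P, A])) for f in feats]
            case = make_case(items)
            feas = feasible_ages(case, kb)
            if feas.is_empty:
                continue
            try:
                post = posterior_age(case, kb_ext)
            except NoConstraintError:
                continue
            span = feas.span()
            for b in post.credible_bins():
                assert b.hi > span.lo and b.lo < span.hi
            checked += 1


class TestAntemortem:
    def test_medullary_haemorrhage_without_cortical_rbc(self, kb):
        case = make_case([("haemorrhage", A, "fracture_line"),
                          ("haemorrhage", P, "medullary")])
        assert classify_antemortem(case, kb) == "antemortem"

    def test_osteocyte_loss_alone_is_antemortem(self, kb):
        assert classify_antemortem(
            make_case([("osteocyte_loss", P)]), kb) == "antemortem"

    def test_absence_is_indeterminate_not_postmortem(self, kb):
        case = make_case([("haemorrhage", U), ("osteocyte_loss", U)])
        assert classify_antemortem(case, kb) == "indeterminate"
        assert classify_antemortem(
            make_case([("haemorrhage", A), ("osteocyte_loss", A)]), kb) \
            == "indeterminate"


class TestPartitionEvents:
    def test_consistent_features_single_event(self, kb):
        part = partition_events(
            make_case([("fibrin", P), ("haemorrhage", P)]), kb)
        assert part.n_events == 1
        assert set(part.groups[0].features) == {"fibrin", "haemorrhage"}

    def test_refracture_through_callus(self, kb):
        # 21-day fracture with a 12-h refracture through bridging callus
        case = make_case([
            ("fracture_union", P), ("calcification", P),
            ("fibrin", P), ("haemorrhage", P),
        ], refracture_through_callus=True)
        part = partition_events(case, kb)
        assert part.n_events == 2
        older, younger = part.groups
        assert older.feasible.contains(21 * 24)
        assert younger.feasible.contains(12)
        assert "fibrin" in younger.features
        assert {"fracture_union", "calcification"} <= set(older.features)

    def test_refracture_flag_forces_two_events_when_consistent(self, kb):
        case = make_case([("fibrin", P), ("haemorrhage", P)],
                         refracture_through_callus=True)
        part = partition_events(case, kb)
        assert part.n_events == 2

    def test_refracture_flag_with_single_feature_adds_unevidenced_event(
            self, kb):
        part = partition_events(
            make_case([("fibrin", P)], refracture_through_callus=True), kb)
        assert part.n_events == 2
        assert part.groups[-1].features == ()

    def test_matches_exhaustive_partition_oracle(self, kb):
        rng = random.Random(23)
        constraint_feats = [tl.feature_id for tl in kb.features
                            if tl.constraint_grade == "constraint"]
        for _ in range(150):
            feats = rng.sample(constraint_feats, rng.randrange(1, 9))
            case = make_case([(f, P) for f in feats])
            part = partition_events(case, kb)
            grids = [grid([(iv.lo, iv.hi) for iv in
                           constraint_for(obs(f, P), kb.feature(f))])
                     for f in sorted(feats)]
            assert part.n_events == min_consistent_k(grids)

    def test_groups_ordered_oldest_first(self, kb):
        part = partition_events(
            make_case([("lamellar_bone", P), ("polymorph_infiltrate", P)]),
            kb)
        assert part.n_events == 2
        spans = [g.feasible.span().lo for g in part.groups]
        assert spans == sorted(spans, reverse=True)


class TestCompareFractures:
    def test_disjoint_ranges_distinguishable(self, kb):
        old = make_case([("lamellar_bone", P)], fracture_id="old")
        new = make_case([("fibrin", P), ("polymorph_infiltrate", A)],
                        fracture_id="new")
        df = compare_fractures([old, new], kb)
        assert df.loc["old", "new"] == "distinguishably_different"
        assert df.loc["new", "old"] == "distinguishably_different"

    def test_overlapping_ranges_indistinguishable(self, kb):
        a = make_case([("woven_osteoid", P)], fracture_id="a")
        b = make_case([("granulation_tissue", P)], fracture_id="b")
        df = compare_fractures([a, b], kb)
        assert df.loc["a", "b"] == "indistinguishable"

    def test_matrix_shape_symmetry_diagonal(self, kb):
        cases = [make_case([("fibrin", P)], fracture_id=f"c{i}")
                 for i in range(4)]
        df = compare_fractures(cases, kb)
        assert df.shape == (4, 4)
        assert (df.values == df.values.T).all()
        assert all(df.loc[i, i] == "indistinguishable" for i in df.index)


class TestEstimateAndCaseIO:
    def test_estimate_assembles_all_verdicts(self, kb):
        est = estimate_age(make_case([("lamellar_bone", P),
                                      ("haemorrhage", P)]), kb)
        assert est.ageable == "ageable"
        assert est.antemortem == "antemortem"
        assert est.reported_range.lo == 672
        assert est.n_events == 1
        assert est.posterior is not None

    def test_restoration_beyond_horizon(self, kb):
        est = estimate_age(make_case([("restoration", P)]), kb)
        assert est.ageable == "beyond_horizon"
        assert est.reported_range is None

    def test_cartilage_only_estimate(self, kb):
        est = estimate_age(make_case([], cartilage_only=True), kb)
        assert est.ageable == "not_ageable_cartilage_only"

    def test_conflicts_reported(self, kb):
        est = estimate_age(make_case([("fibrin", P), ("calcification", P)]),
                           kb)
        assert ("calcification", "fibrin") in est.conflicts
        assert est.n_events == 2

    def test_case_round_trip(self, kb, tmp_path):
        case = make_case([("fibrin", P, "periosteal_away")],
                         fracture_id="rt", mobile=True)
        p = tmp_path / "case.yaml"
        save_case(case, p)
        assert load_case(p) == case

    def test_duplicate_region_observation_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_case([("fibrin", P), ("fibrin", A)])

    def test_cartilage_only_forbids_bone_feature_in_line(self):
        with pytest.raises(ValueError, match="cartilage-only"):
            make_case([("woven_osteoid", P, "fracture_line")],
                      cartilage_only=True)
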