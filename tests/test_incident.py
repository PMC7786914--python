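"""Incident/dynamic AUC, Kaplan-Meier curve and the weighted c-index."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tvroc.cohort import Cohort
from tvroc.errors import UndefinedAUCError, UndefinedStatisticError
from tvroc.incident import (
    analyze_id,
    build_risk_sets,
    concordance,
    id_auc_at,
    id_curve,
    km_curve,
    weekly_id_summary,
)
from tvroc.simulate import SimulationConfig, generate

from conftest import km_oracle, pairwise_auc_oracle, random_instance, subject


class TestBuildRiskSets:
    def test_allocation_rule(self, three_subject_cohort):
        sets = build_risk_sets(three_subject_cohort)
        assert [(r.t, set(r.case_ids), set(r.control_ids)) for r in sets] == [
            (3, {"A"}, {"B", "C"}),
            (5, {"B"}, {"C"}),
        ]

    def test_single_subject_death_has_no_risk_set(self):
        cohort = Cohort.from_records([subject("A", 2, 1)])
        assert build_risk_sets(cohort) == []

    def test_all_censored_gives_empty_list(self):
        cohort = Cohort.from_records([subject("A", 2, 0), subject("B", 5, 0)])
        assert build_risk_sets(cohort) == []


class TestIdAucAt:
    def test_perfect_separation(self):
        assert id_auc_at([5.0], [1.0, 2.0, 3.0]) == 1.0

    def test_pure_ties(self):
        assert id_auc_at([2.0, 2.0], [2.0, 2.0, 2.0]) == 0.5

    def test_eight_pair_enumeration(self):
        # cases {3,7} vs controls {1,4,8,3}: 4.5 of 8 pairs won
        assert id_auc_at([3.0, 7.0], [1.0, 4.0, 8.0, 3.0]) == 0.5625

    def test_empty_group_raises(self):
        with pytest.raises(UndefinedAUCError):
            id_auc_at([], [1.0])

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            cases, controls = random_instance(rng)
            assert id_auc_at(cases, controls) == pytest.approx(
                pairwise_auc_oracle(cases, controls), abs=1e-12
            )

    @given(st.data())
    def test_antisymmetry_under_negation(self, data):
        cases = data.draw(st.lists(st.integers(0, 10), min_size=1, max_size=20))
        controls = data.draw(st.lists(st.integers(0, 10), min_size=1, max_size=20))
        a = id_auc_at(cases, controls)
        b = id_auc_at([-c for c in cases], [-c for c in controls])
        assert a + b == pytest.approx(1.0, abs=1e-12)


class TestIdCurve:
    def test_three_subject_worked_example(self, three_subject_cohort):
        result = id_curve(three_subject_cohort, "lactate", "updated")
        assert [(t, auc) for t, auc, _, _ in result.points] == [(3, 1.0), (5, 1.0)]

    def test_perfect_marker_every_auc_one(self):
        cohort = generate(
            SimulationConfig(n_subjects=200, seed=2, special_mode="perfect_marker")
        )
        for mode in ("baseline", "updated"):
            result = id_curve(cohort, "platelet", mode)
            assert result.points and all(auc == 1.0 for _, auc, _, _ in result.points)

    def test_null_marker_centers_on_half(self):
        cohort = generate(
            SimulationConfig(n_subjects=2000, seed=4, special_mode="null_marker")
        )
        result = id_curve(cohort, "lactate", "updated")
        aucs = np.array([auc for _, auc, _, _ in result.points])
        cases = np.array([n for _, _, n, _ in result.points])
        assert abs(np.average(aucs, weights=cases) - 0.5) < 0.04


class TestKaplanMeier:
    def test_worked_product_limit_example(self, km_worked_cohort):
        curve = km_curve(km_worked_cohort)
        assert curve.survival_at(1) == pytest.approx(3 / 4)
        assert curve.survival_at(3) == pytest.approx(3 / 8)

    def test_no_censoring_reduces_to_empirical(self):
        cohort = Cohort.from_records(
            [subject(f"p{i}", d, 1) for i, d in enumerate([2, 4, 4, 9])]
        )
        curve = km_curve(cohort)
        assert curve.survival_at(2) == pytest.approx(3 / 4)
        assert curve.survival_at(4) == pytest.approx(1 / 4)
        assert curve.survival_at(9) == pytest.approx(0.0)

    def test_all_censored_survival_is_one(self):
        cohort = Cohort.from_records([subject("a", 3, 0), subject("b", 8, 0)])
        curve = km_curve(cohort)
        assert curve.event_days.size == 0
        assert curve.survival_at(5) == 1.0

    def test_matches_hand_oracle_on_random_cohort(self):
        rng = np.random.default_rng(7)
        exits = rng.integers(1, 15, 60)
        events = rng.integers(0, 2, 60)
        cohort = Cohort.from_records(
            [subject(f"p{i}", int(e), int(d)) for i, (e, d) in enumerate(zip(exits, events))]
        )
        curve = km_curve(cohort)
        for t, s in km_oracle(exits, events).items():
            assert curve.survival_at(t) == pytest.approx(s, abs=1e-12)


class TestConcordance:
    def test_constant_unit_auc_gives_one_exactly(self, km_worked_cohort):
        surv = km_curve(km_worked_cohort)
        points = [(1, 1.0, 1, 3), (3, 1.0, 1, 1)]
        assert concordance(points, surv, tau=56) == 1.0

    def test_constant_half_auc_gives_half(self, km_worked_cohort):
        surv = km_curve(km_worked_cohort)
        points = [(1, 0.5, 1, 3), (3, 0.5, 1, 1)]
        assert concordance(points, surv, tau=56) == pytest.approx(0.5)

    def test_worked_weighted_mean(self, km_worked_cohort):
        # raw weights 2*(1/4)*(3/4) and 2*(3/8)*(3/8) -> (4/7, 3/7)
        surv = km_curve(km_worked_cohort)
        points = [(1, 0.8, 1, 3), (3, 0.6, 1, 1)]
        assert concordance(points, surv, tau=56) == pytest.approx(5 / 7, abs=1e-12)

    def test_no_points_before_tau_is_undefined(self, km_worked_cohort):
        surv = km_curve(km_worked_cohort)
        with pytest.raises(UndefinedStatisticError):
            concordance([(10, 0.9, 1, 1)], surv, tau=5)

    def test_cindex_in_convex_hull_of_aucs(self, medium_cohort):
        result = analyze_id(medium_cohort, "lactate", "updated")
        aucs = [auc for t, auc, _, _ in result.points if t <= result.tau]
        assert min(aucs) <= result.cindex <= max(aucs)


class TestWeeklySummary:
    def test_single_event_week_is_identity(self):
        points = [(3, 0.77, 2, 10), (10, 0.66, 1, 8)]
        assert weekly_id_summary(points) == [(1, 0.77, 2), (2, 0.66, 1)]

    def test_event_count_weighting(self):
        points = [(2, 0.9, 2, 10), (5, 0.6, 1, 9)]
        assert weekly_id_summary(points) == [(1, pytest.approx(0.8), 3)]

    def test_empty_weeks_omitted(self):
        points = [(1, 0.7, 1, 5), (50, 0.6, 1, 2)]
        weeks = [w for w, _, _ in weekly_id_summary(points)]
        assert weeks == [1, 8]
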