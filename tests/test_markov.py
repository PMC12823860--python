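"""Markov cohort engine: rate conversions, transitions, propagation, microsim oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strokecea import (
    ModelSpec,
    annual_prob_to_cycle,
    build_cycle_transition,
    microsimulate,
    mortality_for,
    run_cohort,
    run_decision_tree,
    run_strategy,
)


class TestRateConversion:
    def test_zero_maps_to_zero(self):
        assert annual_prob_to_cycle(0.0, 0.25, 5.0) == 0.0

    def test_closed_form_values(self):
        assert annual_prob_to_cycle(0.00760, 0.25, 1.0) == pytest.approx(0.001905, abs=5e-7)
        assert annual_prob_to_cycle(0.00760, 0.25, 2.37) == pytest.approx(0.004510, abs=5e-7)

    def test_certain_event_limit(self):
        assert annual_prob_to_cycle(1.0, 0.25, 1.0) == 1.0

    @settings(derandomize=True, max_examples=50)
    @given(p=st.floats(1e-6, 0.99), hr=st.floats(0.1, 5.0))
    def test_hr_scales_hazard_exactly(self, p, hr):
        p1 = annual_prob_to_cycle(p, 0.25, 1.0)
        p2 = annual_prob_to_cycle(p, 0.25, hr)
        assert -math.log1p(-p2) == pytest.approx(hr * -math.log1p(-p1), rel=1e-9)


class TestMortalityLookup:
    def test_band_lookup_at_start_age(self, default_spec):
        p = mortality_for(64.0, 0, default_spec.life_table, default_spec.mortality, 0.25)
        assert p == pytest.approx(0.001905, abs=5e-7)

    def test_ages_beyond_last_band_use_last_band(self, default_spec):
        p93 = mortality_for(93.0, 0, default_spec.life_table, default_spec.mortality, 0.25)
        assert p93 == annual_prob_to_cycle(0.15120, 0.25, 1.0)

    def test_age_below_first_band_uses_first_band(self, default_spec):
        assert mortality_for(40.0, 0, default_spec.life_table, default_spec.mortality, 0.25) == \
            mortality_for(60.0, 0, default_spec.life_table, default_spec.mortality, 0.25)


class TestCycleTransition:
    def test_identity_without_events(self):
        occ = np.array([0.1, 0.2, 0.3, 0.2, 0.1, 0.05, 0.05])
        nxt, rec, stay, move = build_cycle_transition(occ, np.zeros(6), np.zeros(6), 0.21, 0.5)
        np.testing.assert_allclose(nxt, occ, atol=1e-15)
        assert rec.sum() == 0.0

    def test_total_case_fatality_sends_all_recurrence_to_dead(self):
        occ = np.zeros(7)
        occ[2] = 1.0
        nxt, rec, stay, move = build_cycle_transition(occ, np.zeros(6), np.full(6, 0.1), 1.0, 0.5)
        assert nxt[6] == pytest.approx(0.1, abs=1e-15)
        assert stay.sum() == 0.0 and move.sum() == 0.0

    def test_single_state_hand_arithmetic(self):
        """mRS 3 cohort, d=0.01, r=0.02, cf=0.21, p_stay=0.5."""
        occ = np.zeros(7)
        occ[3] = 1.0
        d = np.full(6, 0.01)
        r = np.full(6, 0.02)
        nxt, rec, stay, move = build_cycle_transition(occ, d, r, 0.21, 0.5)
        assert nxt[6] == pytest.approx(0.01 + 0.99 * 0.02 * 0.21, abs=1e-12)      # 0.014158
        assert move[3] == pytest.approx(0.99 * 0.02 * 0.79 * 0.5, abs=1e-12)      # 0.0078210
        assert nxt[4] == pytest.approx(0.0078210, abs=1e-7)

    def test_mrs5_worsening_capped_at_mrs5(self):
        occ = np.zeros(7)
        occ[5] = 1.0
        nxt, rec, stay, move = build_cycle_transition(occ, np.zeros(6), np.full(6, 0.5), 0.0, 0.0)
        assert nxt[5] == pytest.approx(1.0, abs=1e-15)


def _spec_with(default_spec, **edits) -> ModelSpec:
    doc = default_spec.to_dict()
    for dotted, value in edits.items():
        parts = dotted.split("/")
        target = doc
        for p in parts[:-1]:
            target = target[p]
        target[parts[-1]] = value
    return ModelSpec.from_dict(doc, strict=False)


class TestRunCohort:
    def test_immortal_undiscounted_cohort_conserves_30_years(self, default_spec):
        spec = _spec_with(
            default_spec,
            **{
                "life_table/bands": [[60.0, 0.0]],
                "recurrence/annual_recurrence_by_mrs/values": [0.0] * 6,
                "discount/annual_rate/value": 0.0,
                "utilities/u_mrs/values": [1.0] * 6 + [0.0],
                "comparator/mrs_at_3mo/values": [1.0, 0, 0, 0, 0, 0, 0],
                "comparator/sich_incidence/value": 0.0,
            },
        )
        res = run_strategy(spec, spec.comparator)
        assert res.total_ly == pytest.approx(30.0, abs=1e-9)
        assert res.total_qaly == pytest.approx(30.0, abs=1e-9)

    def test_discounting_strictly_reduces_totals(self, default_spec):
        r0 = run_strategy(default_spec, default_spec.intervention, discount_rate=0.0)
        r5 = run_strategy(default_spec, default_spec.intervention, discount_rate=0.05)
        assert r5.total_qaly < r0.total_qaly
        assert r5.total_ly < r0.total_ly
        assert r5.total_cost < r0.total_cost

    def test_totals_equal_sum_of_trace_increments(self, default_base):
        for res in (default_base.intervention, default_base.comparator):
            assert res.total_cost == pytest.approx(res.trace.cost.sum(), abs=1e-9)
            assert res.total_qaly == pytest.approx(res.trace.qaly.sum(), abs=1e-12)
            assert res.total_ly == pytest.approx(res.trace.ly.sum(), abs=1e-12)

    def test_occupancy_conserved_and_dead_monotone(self, random_spec_factory):
        for seed in range(10):
            spec = random_spec_factory(seed)
            res = run_strategy(spec, spec.intervention)
            sums = res.trace.occupancy.sum(axis=1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-9)
            dead = res.trace.occupancy[:, 6]
            assert np.all(np.diff(dead) >= -1e-15)

    def test_life_years_dominate_qalys(self, default_base):
        assert default_base.intervention.total_ly >= default_base.intervention.total_qaly

    def test_unit_utilities_make_qaly_equal_ly(self, default_spec):
        spec = _spec_with(
            default_spec,
            **{
                "utilities/u_mrs/values": [1.0] * 6 + [0.0],
                "utilities/u_recurrence/value": 1.0,
                "utilities/d_sich/value": 0.0,
            },
        )
        res = run_strategy(spec, spec.intervention)
        assert res.total_qaly == pytest.approx(res.total_ly, abs=1e-12)

    def test_better_initial_distribution_never_reduces_qalys(self, default_spec):
        """Stochastic-dominance monotonicity of the cohort engine."""
        base = run_strategy(default_spec, default_spec.comparator).total_qaly
        doc = default_spec.to_dict()
        p = list(doc["comparator"]["mrs_at_3mo"]["values"])
        p[0] += p[6]
        p[6] = 0.0
        doc["comparator"]["mrs_at_3mo"]["values"] = p
        better = ModelSpec.from_dict(doc, strict=False)
        assert run_strategy(better, better.comparator).total_qaly >= base

    def test_half_cycle_correction_reduces_payoffs_of_shrinking_cohort(self, default_spec):
        on = run_strategy(default_spec, default_spec.intervention)
        doc = default_spec.to_dict()
        doc["config"]["half_cycle_correction"] = False
        off_spec = ModelSpec.from_dict(doc)
        off = run_strategy(off_spec, off_spec.intervention)
        # end-of-cycle weighting undercounts a shrinking cohort, so the
        # trapezoidal correction yields strictly larger life-years
        assert on.total_ly > off.total_ly


class TestMicrosimOracle:
    def test_deterministic_trajectory_matches_cohort(self, default_spec):
        spec = _spec_with(
            default_spec,
            **{
                "life_table/bands": [[60.0, 0.0]],
                "recurrence/annual_recurrence_by_mrs/values": [0.0] * 6,
                "comparator/mrs_at_3mo/values": [1.0, 0, 0, 0, 0, 0, 0],
                "comparator/sich_incidence/value": 0.0,
            },
        )
        tree = run_decision_tree(spec.comparator, spec.costs, spec.utilities)
        coh = run_cohort(tree, spec)
        ms = microsimulate(tree, spec, n_individuals=1, seed=0, strategy=spec.comparator)
        assert ms.total_qaly == pytest.approx(coh.total_qaly, abs=1e-9)
        assert ms.total_cost == pytest.approx(coh.total_cost, abs=1e-6)
        assert ms.total_ly == pytest.approx(coh.total_ly, abs=1e-9)

    def test_same_seed_is_bit_identical(self, default_spec):
        tree = run_decision_tree(default_spec.intervention, default_spec.costs, default_spec.utilities)
        a = microsimulate(tree, default_spec, 2000, seed=9, strategy=default_spec.intervention)
        b = microsimulate(tree, default_spec, 2000, seed=9, strategy=default_spec.intervention)
        assert (a.total_cost, a.total_qaly, a.total_ly) == (b.total_cost, b.total_qaly, b.total_ly)

    def test_converges_to_cohort_totals(self, default_spec):
        """Law-of-large-numbers agreement at moderate n (3 Monte-Carlo SE)."""
        tree = run_decision_tree(default_spec.intervention, default_spec.costs, default_spec.utilities)
        coh = run_cohort(tree, default_spec)
        ms = microsimulate(tree, default_spec, 50_000, seed=123, strategy=default_spec.intervention)
        assert abs(ms.total_cost - coh.total_cost) < 3 * ms.se_cost
        assert abs(ms.total_qaly - coh.total_qaly) < 3 * ms.se_qaly
        assert abs(ms.total_ly - coh.total_ly) < 3 * ms.se_ly
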