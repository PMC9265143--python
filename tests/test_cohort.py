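"""Cohort engine: hazard adjustment, cycle matrices, recursion, microsimulation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import telestroke_cea as tcea
from telestroke_cea.cohort import (
    DEAD_OTHER,
    DEAD_STROKE,
    N_STATES,
    adjust_mortality,
    build_cycle_matrix,
    default_worsening_matrix,
    recurrence_prob,
    resolve_worsening,
    run_cohort,
    run_microsim,
    state_index,
)
from telestroke_cea.config import ConfigError


class TestAdjustMortality:
    def test_identity_under_unit_hazard_ratio(self):
        assert adjust_mortality(0.05, 1.0) == pytest.approx(0.05)

    def test_zero_hazard_stays_zero(self):
        assert adjust_mortality(0.0, 6.55) == 0.0

    def test_closed_form(self):
        # log-survival scale: 1 - (1 - 0.05)**6.55
        assert adjust_mortality(0.05, 6.55) == pytest.approx(1.0 - 0.95**6.55, abs=1e-12)
        assert adjust_mortality(0.05, 6.55) == pytest.approx(0.285356, abs=1e-5)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            adjust_mortality(1.0, 2.0)
        with pytest.raises(ValueError):
            adjust_mortality(0.1, 0.0)

    @given(
        p=st.floats(min_value=0.0, max_value=0.999),
        hr=st.floats(min_value=0.05, max_value=10.0),
    )
    def test_stays_a_probability_and_monotone_in_hr(self, p, hr):
        q = adjust_mortality(p, hr)
        assert 0.0 <= q < 1.0
        assert adjust_mortality(p, hr * 1.5) >= q


class TestRecurrenceProb:
    def test_first_cycle_uses_year1_rate(self, base_cfg):
        assert recurrence_prob(1, False, base_cfg.transition) == pytest.approx(0.0649)

    def test_later_cycles_use_longterm_rate(self, base_cfg):
        assert recurrence_prob(3, False, base_cfg.transition) == pytest.approx(0.0201)

    def test_relative_risk_after_recurrence(self, base_cfg):
        assert recurrence_prob(3, True, base_cfg.transition) == pytest.approx(0.0201 * 1.48)

    def test_capped_at_one(self, base_cfg):
        tp = base_cfg.transition
        tp2 = tcea.TransitionParams(
            p_recur_year1=0.9, p_recur_later=0.9, rr_recur_after_recur=1.48,
            p_death_after_recur=tp.p_death_after_recur, hr_mortality=tp.hr_mortality,
        )
        assert recurrence_prob(1, True, tp2) == 1.0


class TestCycleMatrix:
    def test_rows_stochastic_and_absorbing(self, base_cfg):
        W = resolve_worsening(base_cfg, base_cfg.baselines["control"])
        for cycle in (1, 2, 10, 25):
            M = build_cycle_matrix(cycle, 74 + cycle - 1, base_cfg, worsening=W)
            assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(M >= 0)
            for dead in (DEAD_STROKE, DEAD_OTHER):
                expected = np.zeros(N_STATES)
                expected[dead] = 1.0
                assert np.array_equal(M[dead], expected)

    def test_identity_under_zero_hazards(self, inert_cfg):
        W = resolve_worsening(inert_cfg, inert_cfg.baselines["control"])
        M = build_cycle_matrix(1, 74, inert_cfg, worsening=W)
        assert np.allclose(M, np.eye(N_STATES), atol=1e-15)

    def test_flagged_mass_from_unflagged_mrs2_hand_computed(self, base_cfg):
        """Recurrence-survivor mass = survival share x recurrence x (1 - case fatality)."""
        W = resolve_worsening(base_cfg, base_cfg.baselines["control"])
        age = 75  # cycle 2
        M = build_cycle_matrix(2, age, base_cfg, worsening=W)
        row = M[state_index(2, False)]
        surv = 1.0 - adjust_mortality(base_cfg.life_table[age], 2.17)
        expected = surv * 0.0201 * (1.0 - 0.1783)
        assert row[6:12].sum() == pytest.approx(expected, rel=1e-12)

    def test_no_transition_improves_mrs(self, base_cfg):
        W = resolve_worsening(base_cfg, base_cfg.baselines["control"])
        M = build_cycle_matrix(2, 75, base_cfg, worsening=W)
        for src in range(12):
            for dst in range(12):
                if dst % 6 < src % 6:
                    assert M[src, dst] == 0.0

    def test_missing_life_table_age_raises(self, base_cfg):
        W = resolve_worsening(base_cfg, base_cfg.baselines["control"])
        with pytest.raises(ConfigError, match="age"):
            build_cycle_matrix(1, 60, base_cfg, worsening=W)


def test_default_worsening_matrix_tail_renormalised(base_cfg):
    vec = base_cfg.baselines["control"].mrs_day365
    W = default_worsening_matrix(vec)
    assert np.allclose(W.sum(axis=1), 1.0)
    assert np.all(np.tril(W, k=-1) == 0.0)
    living = vec[:6]
    assert W[2, 3] == pytest.approx(living[3] / living[2:].sum())


class TestRunCohort:
    @pytest.mark.parametrize("arm", ["intervention", "control"])
    def test_conservation_and_monotone_absorption(self, base_cfg, arm):
        trace, events = run_cohort(base_cfg.baselines[arm], base_cfg)
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
        dead = trace.occupancy[:, DEAD_STROKE] + trace.occupancy[:, DEAD_OTHER]
        assert np.all(np.diff(dead) > 0)  # strictly increasing: positive hazards
        assert np.all(events.fatal_recurrences <= events.recurrent_strokes + 1e-15)
        assert np.all(np.diff(events.nursing_home_entries) >= 0)

    def test_first_year_deaths_enter_stroke_death_state(self, base_cfg):
        b = base_cfg.baselines["control"]
        trace, _ = run_cohort(b, base_cfg)
        assert trace.occupancy[0, DEAD_STROKE] == pytest.approx(b.mrs_day365[6])
        assert trace.occupancy[0, :6] == pytest.approx(b.mrs_day365[:6])

    def test_zero_hazards_freeze_occupancy(self, inert_cfg):
        trace, events = run_cohort(inert_cfg.baselines["control"], inert_cfg)
        for t in range(trace.n_cycles + 1):
            assert np.allclose(trace.occupancy[t], trace.occupancy[0], atol=1e-15)
        assert events.recurrent_strokes.sum() == 0.0

    def test_all_mass_dead_is_constant_with_no_events(self, base_cfg):
        baseline = tcea.ArmBaseline(
            arm="control", mrs_day365=np.array([0, 0, 0, 0, 0, 0, 1.0]),
            first12mo_cost_societal=0, first12mo_cost_healthcare=0,
            first12mo_qaly=0, first12mo_ly=0.5,
        )
        trace, events = run_cohort(baseline, base_cfg)
        assert np.all(trace.occupancy[:, DEAD_STROKE] == 1.0)
        assert events.recurrent_strokes.sum() == 0.0
        assert events.nursing_home_entries[-1] == 0.0

    def test_survivor_disability_never_improves(self, base_cfg):
        """Cumulative living mass at mRS <= k can only shrink (no recovery)."""
        trace, _ = run_cohort(base_cfg.baselines["control"], base_cfg)
        living_by_level = trace.occupancy[:, :6] + trace.occupancy[:, 6:12]
        cdf = np.cumsum(living_by_level, axis=1)
        assert np.all(np.diff(cdf, axis=0) <= 1e-12)


class TestMicrosim:
    def test_fixed_seed_reproducible(self, base_cfg):
        a = run_microsim(base_cfg.baselines["control"], base_cfg, 500, seed=3)
        b = run_microsim(base_cfg.baselines["control"], base_cfg, 500, seed=3)
        assert np.array_equal(a[0].occupancy, b[0].occupancy)
        assert np.array_equal(a[1].nursing_home_entries, b[1].nursing_home_entries)

    def test_zero_hazards_retain_initial_state(self, inert_cfg):
        trace, _ = run_microsim(inert_cfg.baselines["control"], inert_cfg, 500, seed=1)
        for t in range(trace.n_cycles + 1):
            assert np.array_equal(trace.occupancy[t], trace.occupancy[0])

    def test_rejects_nonpositive_n(self, base_cfg):
        with pytest.raises(ValueError):
            run_microsim(base_cfg.baselines["control"], base_cfg, 0, seed=1)
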