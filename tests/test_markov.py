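"""Tests for the schedules, cycle matrices and the Markov accumulators."""

import numpy as np
import pytest

from krtcua import (
    HealthState,
    ModelConfig,
    accumulate_costs,
    accumulate_qalys,
    build_cycle_matrix,
    build_schedules,
    discount_factor,
    generate_mortality_schedule,
    run_cohort,
    run_deterministic,
)
from krtcua.markov import InfeasibleRowError, check_trace
from krtcua.params import ArmCosts, CostParam
from krtcua.schedules import CalibrationError
from krtcua.states import ALIVE_STATES, ARM_ACCELERATED, ARM_STANDARD

S = HealthState


class TestMortalitySchedule:
    def test_published_no_ckd_summary(self):
        sched = generate_mortality_schedule(0.022, 0.001, 0.990, 480)
        assert abs(sched.mean - 0.022) < 1e-3
        assert sched.probs.min() >= 0.001
        assert sched.probs.max() <= 0.990

    def test_degenerate_range_gives_constant(self):
        sched = generate_mortality_schedule(0.05, 0.05, 0.05, 100)
        np.testing.assert_allclose(sched.probs, 0.05)

    def test_monotone_nondecreasing(self):
        sched = generate_mortality_schedule(0.03, 0.003, 0.99, 480)
        assert (np.diff(sched.probs) >= -1e-15).all()

    def test_zero_minimum_uses_positive_floor(self):
        sched = generate_mortality_schedule(0.001, 0.0, 0.017, 480)
        assert abs(sched.mean - 0.001) < 1e-3
        assert (sched.probs >= 0).all()

    def test_infeasible_mean_raises(self):
        with pytest.raises(CalibrationError):
            generate_mortality_schedule(0.5, 0.0, 0.017, 480)


class TestDiscounting:
    def test_cycle_zero_undiscounted(self):
        assert discount_factor(0.015, 0, 1 / 12) == 1.0

    def test_one_year(self):
        assert discount_factor(0.015, 12, 1 / 12) == pytest.approx(1 / 1.015)

    def test_forty_years(self):
        assert discount_factor(0.015, 480, 1 / 12) == pytest.approx(1.015 ** -40)


class TestCycleMatrix:
    def test_rows_sum_to_one_and_dead_absorbing(self, params):
        sched = build_schedules(params, 480)
        for cycle in (0, 100, 479):
            m = build_cycle_matrix(params, ARM_STANDARD, cycle, sched)
            np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
            np.testing.assert_allclose(m[S.DEAD], [0, 0, 0, 1])

    def test_krt_row_statics(self, params):
        sched = build_schedules(params, 480)
        m = build_cycle_matrix(params, ARM_ACCELERATED, 0, sched)
        assert m[S.KRT_DEPENDENT, S.NO_CKD] == pytest.approx(0.073)
        assert m[S.KRT_DEPENDENT, S.CKD_NO_KRT] == pytest.approx(0.063)

    def test_arm_specific_recovery_probability(self, params):
        sched = build_schedules(params, 480)
        m_std = build_cycle_matrix(params, ARM_STANDARD, 0, sched)
        m_acc = build_cycle_matrix(params, ARM_ACCELERATED, 0, sched)
        assert m_std[S.CKD_NO_KRT, S.NO_CKD] == pytest.approx(0.139)
        assert m_acc[S.CKD_NO_KRT, S.NO_CKD] == pytest.approx(0.063)

    def test_infeasible_row_raises_with_row_name(self):
        from krtcua.markov import _assemble_matrix

        with pytest.raises(InfeasibleRowError, match="KRT_DEPENDENT"):
            _assemble_matrix(0, 0, 0, 0, 0, 0, 0.5, 0.4, 0.3)


class TestRunCohort:
    def test_identity_matrices_keep_trace_constant(self):
        start = np.array([0.4, 0.3, 0.2, 0.1])
        trace = run_cohort(start, [np.eye(4)] * 10)
        np.testing.assert_allclose(trace, np.tile(start, (11, 1)))

    def test_geometric_decay_closed_form(self):
        # Single alive state with constant 0.5 death probability.
        m = np.eye(4)
        m[0, 0], m[0, 3] = 0.5, 0.5
        trace = run_cohort(np.array([1.0, 0, 0, 0]), [m] * 5)
        np.testing.assert_allclose(trace[:, 0], 0.5 ** np.arange(6))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            run_cohort(np.array([1.0, 0, 0]), [np.eye(4)])
        with pytest.raises(ValueError):
            run_cohort(np.array([1.0, 0, 0, 0]), [np.eye(3)])

    def test_base_case_trace_reaches_absorption(self, params):
        for arm in (ARM_ACCELERATED, ARM_STANDARD):
            res = run_deterministic(params, arm)
            check_trace(res.trace)
            assert res.trace[-1, S.DEAD] > 0.999


def _unit_costs(one_time=0.0, m4=0.0, monthly=0.0):
    zero = CostParam(0.0, 0.0)
    return ArmCosts(
        one_time=CostParam(one_time, 0.0),
        month4_total=CostParam(m4, 0.0),
        monthly_total=CostParam(monthly, 0.0),
        month4_by_state={s: CostParam(m4, 0.0) for s in ALIVE_STATES},
        monthly_by_state={s: CostParam(monthly, 0.0) for s in ALIVE_STATES},
    )


class TestAccumulators:
    def test_everyone_dead_from_cycle_one_accrues_only_entry_cost(self):
        trace = np.zeros((13, 4))
        trace[0] = [1.0, 0, 0, 0]
        trace[1:, S.DEAD] = 1.0
        costs = _unit_costs(one_time=1234.0, m4=99.0, monthly=9.0)
        assert accumulate_costs(trace, costs) == pytest.approx(1234.0)

    def test_pinned_krt_occupancy_hand_sum(self):
        # 12 cycles pinned to the KRT state, no discounting:
        # C0 + month-4 cost + 11 steady monthly costs.
        trace = np.zeros((13, 4))
        trace[:, S.KRT_DEPENDENT] = 1.0
        costs = _unit_costs(one_time=100.0, m4=20.0, monthly=3.0)
        cfg = ModelConfig(n_cycles=12, discount_rate_annual=0.0)
        assert accumulate_costs(trace, costs, config=cfg) == pytest.approx(100 + 20 + 11 * 3)

    def test_discounted_costs_shrink(self):
        trace = np.zeros((13, 4))
        trace[:, S.NO_CKD] = 1.0
        costs = _unit_costs(monthly=100.0, m4=100.0)
        undisc = accumulate_costs(trace, costs, config=ModelConfig(n_cycles=12, discount_rate_annual=0.0))
        disc = accumulate_costs(trace, costs, config=ModelConfig(n_cycles=12, discount_rate_annual=0.05))
        assert disc < undisc

    def test_all_dead_gives_zero_qalys(self):
        trace = np.zeros((11, 4))
        trace[:, S.DEAD] = 1.0
        assert accumulate_qalys(trace, {s: 0.8 for s in ALIVE_STATES}) == 0.0

    def test_full_year_in_no_ckd(self):
        trace = np.zeros((13, 4))
        trace[:, S.NO_CKD] = 1.0
        cfg = ModelConfig(n_cycles=12, discount_rate_annual=0.0)
        u = {S.NO_CKD: 0.85, S.CKD_NO_KRT: 0.74, S.KRT_DEPENDENT: 0.60}
        assert accumulate_qalys(trace, u, cfg) == pytest.approx(0.85)

    def test_utility_outside_unit_interval_rejected(self):
        trace = np.zeros((3, 4))
        trace[:, S.NO_CKD] = 1.0
        with pytest.raises(ValueError):
            accumulate_qalys(trace, {s: 1.2 for s in ALIVE_STATES})


def test_standard_arm_dominates_on_qalys_deterministically(params):
    """With fewer 90-day deaths and the same utilities, the standard arm must
    accumulate more lifetime QALYs in the base case."""
    acc = run_deterministic(params, ARM_ACCELERATED)
    std = run_deterministic(params, ARM_STANDARD)
    assert std.qalys > acc.qalys


def test_half_cycle_correction_changes_little(params):
    cfg = ModelConfig(half_cycle_correction=True)
    plain = run_deterministic(params, ARM_STANDARD)
    hcc = run_deterministic(params, ARM_STANDARD, cfg)
    assert hcc.qalys == pytest.approx(plain.qalys, rel=0.02)
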