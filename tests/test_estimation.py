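"""Unit tests for state classification, transition estimation and MoM fits."""

import math

import numpy as np
import pandas as pd
import pytest

from krtcua import (
    HealthState,
    classify_state,
    compute_state_shares,
    estimate_cost_params,
    estimate_transition_matrix,
    fit_beta_mom,
    fit_gamma_mom,
    period_to_monthly,
)
from krtcua.estimation import ClassificationError, DistributionSpec
from krtcua.states import ARM_ACCELERATED, ARM_STANDARD

from conftest import cohort_frame, make_patient

S = HealthState


class TestClassifyState:
    @pytest.mark.parametrize(
        "alive, krt, egfr, expected",
        [
            (True, False, 75.0, S.NO_CKD),
            (True, False, 60.0, S.NO_CKD),  # boundary belongs to no-CKD
            (True, False, 59.9, S.CKD_NO_KRT),
            (True, True, 80.0, S.KRT_DEPENDENT),  # dialysis dominates eGFR
            (True, True, None, S.KRT_DEPENDENT),
            (False, None, None, S.DEAD),
        ],
    )
    def test_classification(self, alive, krt, egfr, expected):
        assert classify_state(alive, krt, egfr) is expected

    def test_alive_without_egfr_is_an_error(self):
        with pytest.raises(ClassificationError):
            classify_state(True, False, None)


class TestPeriodToMonthly:
    @pytest.mark.parametrize("p, n, expected", [(0.0, 9, 0.0), (1.0, 9, 1.0), (0.75, 2, 0.5)])
    def test_constant_hazard_conversion(self, p, n, expected):
        assert period_to_monthly(p, n) == pytest.approx(expected)

    @pytest.mark.parametrize("p, n", [(1.5, 9), (-0.1, 9), (0.5, 0)])
    def test_domain_errors(self, p, n):
        with pytest.raises(ValueError):
            period_to_monthly(p, n)


class TestBetaMom:
    def test_uniform_case(self):
        spec = fit_beta_mom(0.5, math.sqrt(1.0 / 12.0))
        assert spec.a == pytest.approx(1.0, abs=1e-9)
        assert spec.b == pytest.approx(1.0, abs=1e-9)

    def test_round_trip_through_forward_moments(self):
        forward = DistributionSpec.beta_from_shapes(80.0, 14.40)
        back = fit_beta_mom(forward.mean, forward.sd)
        assert back.a == pytest.approx(80.0, rel=1e-9)
        assert back.b == pytest.approx(14.40, rel=1e-9)

    def test_krt_utility_shapes_imply_published_mean(self):
        # Beta(44.80, 30.00) has mean 44.8/74.8 = 0.599..., printing as 0.60.
        assert round(DistributionSpec.beta_from_shapes(44.80, 30.00).mean, 2) == 0.60

    @pytest.mark.parametrize("mean, sd", [(0.5, 0.5), (0.0, 0.1), (1.0, 0.1), (0.5, 0.0)])
    def test_infeasible_moments_raise(self, mean, sd):
        with pytest.raises(ValueError):
            fit_beta_mom(mean, sd)


class TestGammaMom:
    def test_mean_equal_sd_is_exponential(self):
        assert fit_gamma_mom(5.0, 5.0).a == pytest.approx(1.0)

    def test_published_first_period_cost(self):
        spec = fit_gamma_mom(182_626.0, 175_710.0)
        assert spec.a * spec.b == pytest.approx(182_626.0, rel=1e-6)

    def test_round_trip_through_forward_moments(self):
        forward = DistributionSpec.gamma_from_shapes(2.5, 1234.0)
        back = fit_gamma_mom(forward.mean, forward.sd)
        assert back.a == pytest.approx(2.5, rel=1e-9)
        assert back.b == pytest.approx(1234.0, rel=1e-9)

    @pytest.mark.parametrize("mean, sd", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0)])
    def test_domain_errors(self, mean, sd):
        with pytest.raises(ValueError):
            fit_gamma_mom(mean, sd)


def test_distribution_spec_rejects_inconsistent_moments():
    with pytest.raises(ValueError):
        DistributionSpec("beta", 2.0, 2.0, mean=0.9, sd=0.1)


class TestTransitionMatrix:
    def test_stayers_give_identity_period_matrix(self):
        rows = [
            make_patient("a", egfr_90=80, egfr_365=80),
            make_patient("b", egfr_90=40, egfr_365=40),
            make_patient("c", krt_90=1.0, krt_365=1.0, egfr_90=30, egfr_365=30),
        ]
        est = estimate_transition_matrix(cohort_frame(rows))
        np.testing.assert_allclose(est.matrix_period, np.eye(4), atol=1e-12)
        np.testing.assert_allclose(est.matrix_monthly, np.eye(4), atol=1e-12)

    def test_direct_count_proportion(self):
        # 10 no-CKD patients at day 90, 4 dead at 365 -> period P(1->4) = 0.4.
        rows = [
            make_patient(f"p{i}", egfr_90=80, egfr_365=80, alive_365=(i >= 4))
            for i in range(10)
        ]
        est = estimate_transition_matrix(cohort_frame(rows))
        assert est.matrix_period[S.NO_CKD, S.DEAD] == pytest.approx(0.4)
        assert est.counts[S.NO_CKD].sum() == 10

    def test_decedent_contributes_only_to_absorbing_row(self):
        rows = [make_patient("d", alive_90=False), make_patient("a", egfr_90=80, egfr_365=80)]
        est = estimate_transition_matrix(cohort_frame(rows))
        np.testing.assert_allclose(est.matrix_period[S.DEAD], [0, 0, 0, 1])
        np.testing.assert_allclose(est.matrix_monthly[S.DEAD], [0, 0, 0, 1])

    def test_rows_are_stochastic_and_counts_conserved(self, two_arm_cohort):
        est = estimate_transition_matrix(two_arm_cohort)
        est.require_estimable()
        np.testing.assert_allclose(est.matrix_period.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(est.matrix_monthly.sum(axis=1), 1.0, atol=1e-9)
        # Row sums of counts equal day-90 occupancy (here 12 patients total).
        assert est.counts.sum() == len(two_arm_cohort)

    def test_unoccupied_row_is_flagged_not_zero_filled(self):
        rows = [make_patient("a", egfr_90=80, egfr_365=80)]  # nobody in KRT or CKD
        est = estimate_transition_matrix(cohort_frame(rows))
        assert S.KRT_DEPENDENT in est.inestimable_rows
        assert np.isnan(est.matrix_period[S.KRT_DEPENDENT, 0])
        with pytest.raises(ValueError):
            est.require_estimable()


class TestCostParams:
    def test_degenerate_share_puts_everything_on_krt(self, two_arm_cohort):
        table = estimate_cost_params(two_arm_cohort, state_shares=(1.0, 0.0, 0.0))
        by_state = table[ARM_ACCELERATED]["monthly_cost_121_365"]["by_state"]
        total = table[ARM_ACCELERATED]["monthly_cost_121_365"]["mean"]
        assert by_state["KRT_DEPENDENT"]["mean"] == pytest.approx(total)
        assert by_state["NO_CKD"]["mean"] == 0.0

    def test_constant_costs_have_zero_sd(self):
        rows = [make_patient(f"p{i}", cost_0_90=500.0) for i in range(5)]
        rows += [make_patient(f"s{i}", arm=ARM_STANDARD, cost_0_90=500.0) for i in range(5)]
        table = estimate_cost_params(cohort_frame(rows))
        assert table[ARM_ACCELERATED]["cost_0_90"]["mean"] == pytest.approx(500.0)
        assert table[ARM_ACCELERATED]["cost_0_90"]["sd"] == 0.0

    def test_shares_must_sum_to_one(self, two_arm_cohort):
        with pytest.raises(ValueError):
            estimate_cost_params(two_arm_cohort, state_shares=(0.5, 0.5, 0.5))


class TestStateShares:
    def test_all_cost_in_krt_state(self):
        rows = [
            make_patient("k", krt_90=1.0, krt_365=1.0, egfr_90=30, egfr_365=30,
                         monthly_cost_121_365=100.0),
            make_patient("n", egfr_90=80, egfr_365=80, monthly_cost_121_365=0.0),
        ]
        assert compute_state_shares(cohort_frame(rows)) == pytest.approx((1.0, 0.0, 0.0))

    def test_two_equal_states_split_evenly(self):
        rows = [
            make_patient("k", krt_90=1.0, krt_365=1.0, egfr_90=30, egfr_365=30,
                         monthly_cost_121_365=100.0),
            make_patient("c", egfr_90=40, egfr_365=40, monthly_cost_121_365=100.0),
            make_patient("n", egfr_90=80, egfr_365=80, monthly_cost_121_365=0.0),
        ]
        assert compute_state_shares(cohort_frame(rows)) == pytest.approx((0.5, 0.5, 0.0))

    def test_zero_total_cost_is_undefined(self):
        rows = [make_patient("n", monthly_cost_121_365=0.0)]
        with pytest.raises(ValueError):
            compute_state_shares(cohort_frame(rows))
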