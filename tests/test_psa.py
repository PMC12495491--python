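"""Tests for the probabilistic sensitivity analysis and scenario engine."""

import numpy as np
import pytest

from krtcua import (
    HealthState,
    ModelConfig,
    ceac_threshold,
    compute_icer,
    compute_inmb,
    default_parameters,
    run_deterministic,
    run_psa,
    sample_draw,
    scenario_equal_costs,
    scenario_start_states,
)
from krtcua.params import BetaParam, CostParam, replace
from krtcua.psa import DOMINANT, DOMINATED, UNDEFINED, _sample_all
from krtcua.markov import build_schedules
from krtcua.states import ALIVE_STATES, ARM_ACCELERATED, ARM_STANDARD, ARMS

S = HealthState


class TestIcer:
    @pytest.mark.parametrize(
        "dc, dq, expected",
        [
            (-16_041.0, 0.77, DOMINANT),
            (19_852.0, -0.5, DOMINATED),
            (5.0, 0.0, UNDEFINED),
            (0.0, 1.0, 0.0),
        ],
    )
    def test_quadrant_flags(self, dc, dq, expected):
        assert compute_icer(dc, dq) == expected

    def test_ratio_of_printed_rounded_increments(self):
        assert compute_icer(19_852.0, 0.86) == pytest.approx(19_852.0 / 0.86)
        assert compute_icer(19_852.0, 0.86) == pytest.approx(23_084, abs=1.0)


class TestInmb:
    def test_breakeven(self):
        assert compute_inmb(50_000.0, 1.0, 50_000.0) == 0.0

    def test_printed_rounded_increments(self):
        assert compute_inmb(19_852.0, 0.86, 50_000.0) == pytest.approx(23_148.0)

    def test_sign_flips_exactly_at_icer(self):
        dc, dq = 20_000.0, 0.8
        icer = compute_icer(dc, dq)
        assert compute_inmb(dc, dq, icer) == pytest.approx(0.0, abs=1e-9)
        assert compute_inmb(dc, dq, icer + 1) > 0
        assert compute_inmb(dc, dq, icer - 1) < 0

    def test_nonpositive_wtp_rejected(self):
        with pytest.raises(ValueError):
            compute_inmb(1.0, 1.0, 0.0)


class TestCeacThreshold:
    def test_always_cost_effective_has_no_crossing(self):
        assert ceac_threshold([0, 10_000, 20_000], [1.0, 1.0, 1.0]) is None
        assert ceac_threshold([0, 10_000], [0.1, 0.2]) is None

    def test_linear_interpolation(self):
        assert ceac_threshold([30_000, 40_000], [0.4, 0.6]) == pytest.approx(35_000.0)

    def test_exact_grid_point(self):
        assert ceac_threshold([0, 10_000, 20_000], [0.2, 0.5, 0.9]) == 10_000.0


@pytest.fixture(scope="module")
def psa_result(params):
    return run_psa(params, ModelConfig(), n_sims=400, seed=123)


class TestRunPsa:
    def test_requires_two_draws(self, params):
        with pytest.raises(ValueError):
            run_psa(params, n_sims=1)

    def test_inmb_identity_on_every_draw(self, psa_result):
        d = psa_result.draws
        np.testing.assert_allclose(
            d["inmb"], psa_result.wtp * d["delta_qaly"] - d["delta_cost"], atol=1e-6
        )
        assert psa_result.inmb == pytest.approx(
            psa_result.wtp * psa_result.delta_qaly - psa_result.delta_cost, abs=1e-6
        )

    def test_ceac_at_zero_is_probability_of_saving(self, psa_result):
        p0 = psa_result.ceac_probs[0]
        assert p0 == pytest.approx((psa_result.draws["delta_cost"] < 0).mean())

    def test_ceac_nondecreasing_when_all_gains_positive(self, psa_result):
        if (psa_result.draws["delta_qaly"] > 0).all():
            assert (np.diff(psa_result.ceac_probs) >= 0).all()

    def test_credible_interval_orders(self, psa_result):
        lo, hi = psa_result.inmb_cri
        assert lo < psa_result.inmb < hi
        mlo, mhi = psa_result.inmb_mean_ci
        assert (mhi - mlo) < (hi - lo)  # mean-level interval is much tighter

    def test_fixed_seed_reproducible(self, params):
        a = run_psa(params, n_sims=50, seed=7, include_deterministic=False)
        b = run_psa(params, n_sims=50, seed=7, include_deterministic=False)
        assert a.draws.equals(b.draws)


def _degenerate_params():
    """Base-case parameters with (almost) all sampling variance removed."""
    p = default_parameters()
    kappa = 1e9

    def freeze_beta(bp: BetaParam) -> BetaParam:
        return BetaParam(bp.mean, bp.mean * kappa, (1.0 - bp.mean) * kappa)

    def freeze_costs(c):
        from krtcua.params import ArmCosts

        return ArmCosts(
            one_time=CostParam(c.one_time.mean, 0.0),
            month4_total=CostParam(c.month4_total.mean, 0.0),
            monthly_total=CostParam(c.monthly_total.mean, 0.0),
            month4_by_state={s: CostParam(v.mean, 0.0) for s, v in c.month4_by_state.items()},
            monthly_by_state={s: CostParam(v.mean, 0.0) for s, v in c.monthly_by_state.items()},
        )

    return replace(
        p,
        utilities={s: freeze_beta(b) for s, b in p.utilities.items()},
        static_shared={k: freeze_beta(b) for k, b in p.static_shared.items()},
        static_by_arm={
            k: {arm: freeze_beta(b) for arm, b in d.items()} for k, d in p.static_by_arm.items()
        },
        costs={arm: freeze_costs(c) for arm, c in p.costs.items()},
    )


def test_psa_collapses_to_deterministic_run_without_variance():
    """With degenerate distributions every draw equals the mean run."""
    params = _degenerate_params()
    res = run_psa(params, n_sims=5, seed=0, timedep_cv_scale=0.0)
    for arm in ARMS:
        det = run_deterministic(params, arm)
        assert res.arms[arm]["cost_mean"] == pytest.approx(det.cost, rel=1e-4)
        assert res.arms[arm]["qaly_mean"] == pytest.approx(det.qalys, rel=1e-4)
        # residual spread comes only from the near-degenerate betas
        assert res.arms[arm]["cost_sd"] / res.arms[arm]["cost_mean"] < 1e-4


def test_monte_carlo_error_scales_as_inverse_sqrt_n(params):
    """The spread of the PSA mean over replicates should halve when the
    number of draws quadruples."""
    cfg = ModelConfig(n_cycles=24)
    means_small, means_large = [], []
    for rep in range(12):
        means_small.append(
            run_psa(params, cfg, n_sims=40, seed=1000 + rep, include_deterministic=False).delta_cost
        )
        means_large.append(
            run_psa(params, cfg, n_sims=160, seed=2000 + rep, include_deterministic=False).delta_cost
        )
    ratio = np.std(means_small) / np.std(means_large)
    assert 1.2 < ratio < 3.3  # expect ~2


class TestSampling:
    def test_utility_draws_match_beta_moments(self, params):
        sched = build_schedules(params, 24)
        rng = np.random.default_rng(0)
        d = _sample_all(params, sched, 5000, rng, 1.0)
        u = d["utilities"][:, 0]  # no-CKD state, Beta(80, 14.4)
        mean = 80.0 / 94.4
        sd = np.sqrt(80 * 14.4 / (94.4 ** 2 * 95.4))
        assert abs(u.mean() - mean) < 3 * sd / np.sqrt(5000)

    def test_shared_parameters_identical_across_arms(self, params):
        rng = np.random.default_rng(1)
        draw = sample_draw(params, rng, ModelConfig(n_cycles=24))
        shared = draw.statics[(S.KRT_DEPENDENT, S.NO_CKD)]
        assert shared[ARM_ACCELERATED] == shared[ARM_STANDARD]
        arm_specific = draw.statics[(S.CKD_NO_KRT, S.NO_CKD)]
        assert arm_specific[ARM_ACCELERATED] != arm_specific[ARM_STANDARD]

    def test_timedep_scale_zero_reproduces_schedule(self, params):
        cfg = ModelConfig(n_cycles=24)
        sched = build_schedules(params, cfg.n_cycles)
        rng = np.random.default_rng(2)
        draw = sample_draw(params, rng, cfg, schedules=sched, timedep_cv_scale=0.0)
        np.testing.assert_allclose(draw.death[S.NO_CKD], sched.death[S.NO_CKD].probs)

    def test_sample_draw_reproducible(self, params):
        cfg = ModelConfig(n_cycles=24)
        d1 = sample_draw(params, np.random.default_rng(5), cfg)
        d2 = sample_draw(params, np.random.default_rng(5), cfg)
        assert d1.utilities == d2.utilities
        np.testing.assert_array_equal(d1.nockd_ckd, d2.nockd_ckd)


class TestScenarios:
    def test_identity_scenario_equals_base(self, params):
        base = run_psa(params, n_sims=60, seed=9, include_deterministic=False)
        same = scenario_start_states(
            params,
            krt_share_acc=params.start[ARM_ACCELERATED].krt_share_survivors,
            krt_share_std=params.start[ARM_STANDARD].krt_share_survivors,
            n_sims=60,
            seed=9,
            include_deterministic=False,
        )
        assert base.draws.equals(same.draws)

    def test_higher_krt_share_lowers_accelerated_qalys(self, params):
        base = run_psa(params, n_sims=200, seed=21, include_deterministic=False)
        shifted = scenario_start_states(
            params, krt_share_acc=0.104, krt_share_std=0.060,
            n_sims=200, seed=21, include_deterministic=False,
        )
        assert shifted.arms[ARM_ACCELERATED]["qaly_mean"] < base.arms[ARM_ACCELERATED]["qaly_mean"]
        # standard remains the more effective strategy
        assert shifted.delta_qaly > 0

    def test_pooled_monthly_cost_arithmetic(self, params):
        pooled = params.with_pooled_monthly_costs()
        assert pooled.costs[ARM_ACCELERATED].monthly_total.mean == pytest.approx(
            (3_293 + 5_558) / 2
        )
        assert pooled.costs[ARM_ACCELERATED].monthly_total.mean == pooled.costs[
            ARM_STANDARD
        ].monthly_total.mean
        # one-time costs untouched
        assert pooled.costs[ARM_ACCELERATED].one_time.mean == 182_626

    def test_pooling_already_equal_arms_changes_nothing(self, params):
        equal = params.with_pooled_monthly_costs()
        again = equal.with_pooled_monthly_costs()
        assert again.costs == equal.costs

    def test_invalid_share_rejected(self, params):
        with pytest.raises(ValueError):
            scenario_start_states(params, krt_share_acc=1.5)
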