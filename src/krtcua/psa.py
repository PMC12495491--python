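"""Probabilistic sensitivity analysis and scenario engine.

Parameter uncertainty is propagated by Monte Carlo: utilities and static
transition probabilities are drawn from their beta distributions (the
published shape parameters), costs from method-of-moments gamma fits, and
each cycle's time-dependent probability from a per-cycle beta whose mean is
the calibrated schedule value.  Each draw runs the lifetime Markov model for
both arms — parameters that are not arm-specific (utilities, shared
transition probabilities, the death schedules) use the same draw in both
arms, so incremental results reflect only genuine between-arm evidence.

Outputs are collected in :class:`CUAResult`: per-arm means/SDs, incremental
cost and QALYs, the ICER (or a dominance flag), the incremental net monetary
benefit with its 95% credible interval, and the cost-effectiveness
acceptability curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .markov import (
    ModelConfig,
    ModelSchedules,
    build_schedules,
    discount_factors,
    run_deterministic,
)
from .params import ModelParameters, starting_distribution
from .states import ALIVE_STATES, ARM_ACCELERATED, ARM_STANDARD, ARMS, N_STATES, HealthState

logger = logging.getLogger(__name__)

__all__ = [
    "PsaDraw",
    "CUAResult",
    "sample_draw",
    "run_psa",
    "compute_icer",
    "compute_inmb",
    "ceac_threshold",
    "scenario_start_states",
    "scenario_equal_costs",
    "DOMINANT",
    "DOMINATED",
    "UNDEFINED",
    "default_lambda_grid",
]

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"


def default_lambda_grid() -> np.ndarray:
    """Willingness-to-pay grid for the CEAC: $0 to $100,000 in $1,000 steps."""
    return np.arange(0.0, 100_001.0, 1_000.0)


def compute_icer(delta_cost: float, delta_qaly: float) -> float | str:
    """ICER = ΔC/ΔQ with quadrant flags instead of exceptions.

    Cheaper-and-better is ``"dominant"``, costlier-and-worse ``"dominated"``,
    ΔQ = 0 ``"undefined"``.
    """
    if delta_qaly == 0.0:
        return UNDEFINED
    if delta_cost < 0.0 and delta_qaly > 0.0:
        return DOMINANT
    if delta_cost > 0.0 and delta_qaly < 0.0:
        return DOMINATED
    return delta_cost / delta_qaly


def compute_inmb(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Incremental net monetary benefit λ·ΔQ − ΔC at willingness-to-pay λ."""
    if wtp <= 0:
        raise ValueError("willingness-to-pay must be positive")
    return wtp * delta_qaly - delta_cost


def ceac_threshold(lambdas: np.ndarray, probs: np.ndarray) -> float | None:
    """The λ at which the acceptability curve crosses probability 0.5.

    Linear interpolation at the first crossing; ``None`` when the curve never
    crosses (e.g. the strategy is cost-effective, or not, at every λ).
    """
    lambdas = np.asarray(lambdas, dtype=float)
    probs = np.asarray(probs, dtype=float)
    d = probs - 0.5
    for i in range(len(d) - 1):
        if d[i] == 0.0:
            return float(lambdas[i])
        if d[i] * d[i + 1] < 0.0:
            frac = d[i] / (d[i] - d[i + 1])
            return float(lambdas[i] + frac * (lambdas[i + 1] - lambdas[i]))
    if d[-1] == 0.0:
        return float(lambdas[-1])
    return None


# ---------------------------------------------------------------------------
# sampling


def _beta_by_moments_arrays(
    mean: np.ndarray, sd: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized beta-by-moments; returns (alpha, beta, feasible mask)."""
    var = sd * sd
    bound = mean * (1.0 - mean)
    feasible = (var > 0.0) & (var < bound)
    nu = np.where(feasible, bound / np.where(var > 0, var, 1.0) - 1.0, 1.0)
    return mean * nu, (1.0 - mean) * nu, feasible


def _sample_timedep(
    rng: np.random.Generator,
    schedule: np.ndarray,
    cv: float,
    n_sims: int,
) -> tuple[np.ndarray, int]:
    """Sample per-cycle probabilities around a calibrated schedule.

    Cycle t is drawn from a beta with mean = schedule[t] and
    SD = cv * schedule[t]; cycles with infeasible beta moments fall back to a
    [0, 1]-truncated normal (count returned for logging); cv = 0 reproduces
    the schedule exactly.
    """
    n_cycles = schedule.shape[0]
    if cv == 0.0:
        return np.broadcast_to(schedule, (n_sims, n_cycles)).copy(), 0
    sd = cv * schedule
    alpha, beta, feasible = _beta_by_moments_arrays(schedule, sd)
    out = np.empty((n_sims, n_cycles))
    degenerate = sd == 0.0
    fallback = ~feasible & ~degenerate
    ok = feasible
    if ok.any():
        out[:, ok] = rng.beta(alpha[ok][None, :], beta[ok][None, :], (n_sims, int(ok.sum())))
    if degenerate.any():
        out[:, degenerate] = schedule[degenerate][None, :]
    n_fallback = int(fallback.sum())
    if n_fallback:
        idx = np.flatnonzero(fallback)
        for t in idx:
            m, s = schedule[t], sd[t]
            a, b = (0.0 - m) / s, (1.0 - m) / s
            out[:, t] = stats.truncnorm.rvs(a, b, loc=m, scale=s, size=n_sims, random_state=rng)
        logger.info("truncated-normal fallback used for %d cycles", n_fallback)
    return out, n_fallback


def _sample_beta_param(rng: np.random.Generator, p, n: int) -> np.ndarray:
    return rng.beta(p.a, p.b, n)


def _sample_cost(rng: np.random.Generator, c, n: int) -> np.ndarray:
    if c.sd == 0.0:
        return np.full(n, c.mean, dtype=float)
    if c.mean == 0.0:
        return np.zeros(n)
    k = (c.mean / c.sd) ** 2
    theta = c.sd * c.sd / c.mean
    return rng.gamma(k, theta, n)


def _sample_all(
    params: ModelParameters,
    schedules: ModelSchedules,
    n_sims: int,
    rng: np.random.Generator,
    timedep_cv_scale: float,
) -> dict:
    """Draw every sampled quantity for ``n_sims`` simulations.

    Sampling order is fixed, so a seed fully determines the draw set.
    Quantities without an arm split are drawn once and shared by both arms.
    """
    S = HealthState
    out: dict = {"n_fallback_cycles": 0}
    out["utilities"] = np.column_stack(
        [_sample_beta_param(rng, params.utilities[s], n_sims) for s in ALIVE_STATES]
    )
    statics: dict = {}
    for key, p in params.static_shared.items():
        statics[key] = {arm: None for arm in ARMS}
        shared = _sample_beta_param(rng, p, n_sims)
        for arm in ARMS:
            statics[key][arm] = shared
    for key, per_arm in params.static_by_arm.items():
        statics[key] = {arm: _sample_beta_param(rng, per_arm[arm], n_sims) for arm in ARMS}
    out["statics"] = statics

    out["death"] = {}
    for s in ALIVE_STATES:
        sched = schedules.death[s]
        draws, nf = _sample_timedep(
            rng, sched.probs, sched.cv * timedep_cv_scale, n_sims
        )
        out["death"][s] = draws
        out["n_fallback_cycles"] += nf
    sched = schedules.nockd_to_ckd
    out["nockd_ckd"], nf = _sample_timedep(
        rng, sched.probs, sched.cv * timedep_cv_scale, n_sims
    )
    out["n_fallback_cycles"] += nf

    out["costs"] = {
        arm: {
            "one_time": _sample_cost(rng, params.costs[arm].one_time, n_sims),
            "month4": np.column_stack(
                [_sample_cost(rng, params.costs[arm].month4_by_state[s], n_sims) for s in ALIVE_STATES]
            ),
            "monthly": np.column_stack(
                [_sample_cost(rng, params.costs[arm].monthly_by_state[s], n_sims) for s in ALIVE_STATES]
            ),
        }
        for arm in ARMS
    }
    return out


@dataclass
class PsaDraw:
    """One Monte Carlo parameter draw (per-arm where arm-specific)."""

    index: int
    utilities: dict[HealthState, float]
    statics: dict[tuple[HealthState, HealthState], dict[str, float]]
    death: dict[HealthState, np.ndarray]
    nockd_ckd: np.ndarray
    costs: dict[str, dict]

    def __post_init__(self) -> None:
        for s, u in self.utilities.items():
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"utility[{s.name}] = {u} outside [0, 1]")
        for arm in self.costs:
            if self.costs[arm]["one_time"] < 0:
                raise ValueError("negative sampled cost")


def sample_draw(
    params: ModelParameters,
    rng: np.random.Generator,
    config: ModelConfig | None = None,
    schedules: ModelSchedules | None = None,
    timedep_cv_scale: float = 1.0,
    index: int = 0,
) -> PsaDraw:
    """Draw a single PSA parameter set (same distributions as :func:`run_psa`)."""
    config = config or ModelConfig()
    schedules = schedules or build_schedules(params, config.n_cycles)
    d = _sample_all(params, schedules, 1, rng, timedep_cv_scale)
    return PsaDraw(
        index=index,
        utilities={s: float(d["utilities"][0, i]) for i, s in enumerate(ALIVE_STATES)},
        statics={k: {arm: float(v[arm][0]) for arm in ARMS} for k, v in d["statics"].items()},
        death={s: d["death"][s][0] for s in ALIVE_STATES},
        nockd_ckd=d["nockd_ckd"][0],
        costs={
            arm: {
                "one_time": float(d["costs"][arm]["one_time"][0]),
                "month4": {s: float(d["costs"][arm]["month4"][0, i]) for i, s in enumerate(ALIVE_STATES)},
                "monthly": {s: float(d["costs"][arm]["monthly"][0, i]) for i, s in enumerate(ALIVE_STATES)},
            }
            for arm in ARMS
        },
    )


# ---------------------------------------------------------------------------
# batched model evaluation


def _propagate_arm(
    draws: dict,
    arm: str,
    start: np.ndarray,
    config: ModelConfig,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Run the lifetime model for one arm for every draw at once.

    Returns per-draw (cost, qalys) and the number of cycle-rows whose sampled
    off-diagonal probabilities exceeded 1 and were renormalized.
    """
    S = HealthState
    n_sims = draws["utilities"].shape[0]
    n_cycles = draws["nockd_ckd"].shape[1]
    disc = discount_factors(config, n_cycles + 1)

    statics = draws["statics"]
    nockd_krt = statics[(S.NO_CKD, S.KRT_DEPENDENT)][arm]
    ckd_nockd = statics[(S.CKD_NO_KRT, S.NO_CKD)][arm]
    ckd_krt = statics[(S.CKD_NO_KRT, S.KRT_DEPENDENT)][arm]
    krt_nockd = statics[(S.KRT_DEPENDENT, S.NO_CKD)][arm]
    krt_ckd = statics[(S.KRT_DEPENDENT, S.CKD_NO_KRT)][arm]
    death = draws["death"]
    nockd_ckd = draws["nockd_ckd"]

    util = draws["utilities"]  # (n, 3)
    arm_costs = draws["costs"][arm]
    month4 = arm_costs["month4"]  # (n, 3)
    monthly = arm_costs["monthly"]

    occ = np.broadcast_to(start, (n_sims, N_STATES)).copy()
    cost = arm_costs["one_time"].copy()
    qalys = np.zeros(n_sims)
    n_renorm = 0

    m = np.zeros((n_sims, N_STATES, N_STATES))
    m[:, S.DEAD, S.DEAD] = 1.0
    for t in range(n_cycles):
        m[:, S.NO_CKD, S.CKD_NO_KRT] = nockd_ckd[:, t]
        m[:, S.NO_CKD, S.KRT_DEPENDENT] = nockd_krt
        m[:, S.NO_CKD, S.DEAD] = death[S.NO_CKD][:, t]
        m[:, S.CKD_NO_KRT, S.NO_CKD] = ckd_nockd
        m[:, S.CKD_NO_KRT, S.KRT_DEPENDENT] = ckd_krt
        m[:, S.CKD_NO_KRT, S.DEAD] = death[S.CKD_NO_KRT][:, t]
        m[:, S.KRT_DEPENDENT, S.NO_CKD] = krt_nockd
        m[:, S.KRT_DEPENDENT, S.CKD_NO_KRT] = krt_ckd
        m[:, S.KRT_DEPENDENT, S.DEAD] = death[S.KRT_DEPENDENT][:, t]
        for s in ALIVE_STATES:
            m[:, s, s] = 0.0
            off = m[:, s, :].sum(axis=1)
            bad = off > 1.0
            if bad.any():
                n_renorm += int(bad.sum())
                m[bad, s, :] /= off[bad, None]
                off = np.minimum(off, 1.0)
            m[:, s, s] = 1.0 - off
        occ_new = np.einsum("ni,nij->nj", occ, m)
        weights = 0.5 * (occ + occ_new) if config.half_cycle_correction else occ_new
        alive_occ = weights[:, : len(ALIVE_STATES)]
        cvec = month4 if t == 0 else monthly
        cost += disc[t + 1] * np.einsum("ns,ns->n", alive_occ, cvec)
        qalys += disc[t + 1] * config.cycle_length * np.einsum("ns,ns->n", alive_occ, util)
        occ = occ_new
    return cost, qalys, n_renorm


@dataclass
class CUAResult:
    """Cost-utility analysis results from one PSA run.

    Increments are standard minus accelerated.  ``icer`` is the ratio of mean
    increments or a dominance flag; ``inmb`` and its credible interval are
    evaluated at ``wtp``; the CEAC gives, for each λ on the grid, the share
    of draws in which standard initiation has positive net benefit.
    """

    arms: dict[str, dict[str, float]]
    delta_cost: float
    delta_qaly: float
    delta_cost_sd: float
    delta_qaly_sd: float
    icer: float | str
    inmb: float
    inmb_cri: tuple[float, float]
    wtp: float
    ceac_lambdas: np.ndarray
    ceac_probs: np.ndarray
    n_sims: int
    seed: int | None
    draws: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)
    deterministic: dict | None = None

    @property
    def ceac_crossing(self) -> float | None:
        return ceac_threshold(self.ceac_lambdas, self.ceac_probs)

    @property
    def inmb_mean_ci(self) -> tuple[float, float]:
        """95% interval on the *expected* INMB (mean ± 1.96 SD/√n).

        The per-draw percentile interval ``inmb_cri`` describes parameter
        uncertainty in the incremental net benefit itself; this much narrower
        interval describes Monte-Carlo uncertainty in its mean, which is what
        narrow published intervals around a mean INMB usually are.
        """
        half = 1.96 * self.draws["inmb"].std(ddof=1) / np.sqrt(self.n_sims)
        return (self.inmb - half, self.inmb + half)

    def ceac_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.ceac_lambdas, "p_cost_effective": self.ceac_probs})


def run_psa(
    params: ModelParameters,
    config: ModelConfig | None = None,
    n_sims: int = 5000,
    seed: int | None = None,
    lambda_grid: np.ndarray | None = None,
    timedep_cv_scale: float = 1.0,
    include_deterministic: bool = True,
) -> CUAResult:
    """Run the full probabilistic cost-utility analysis.

    ``timedep_cv_scale`` scales the per-cycle sampling SD of the
    time-dependent probabilities (0 freezes them at the calibrated schedule).
    """
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    config = config or ModelConfig()
    lambdas = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
    rng = np.random.default_rng(seed)
    schedules = build_schedules(params, config.n_cycles)
    draws = _sample_all(params, schedules, n_sims, rng, timedep_cv_scale)

    per_arm: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    n_renorm = 0
    for arm in ARMS:
        start = starting_distribution(
            params.start[arm], include_decedents=config.include_decedents_in_start
        )
        cost, qalys, nr = _propagate_arm(draws, arm, start, config)
        per_arm[arm] = (cost, qalys)
        n_renorm += nr
    if n_renorm:
        logger.info("renormalized %d sampled transition rows with mass > 1", n_renorm)

    cost_a, qaly_a = per_arm[ARM_ACCELERATED]
    cost_s, qaly_s = per_arm[ARM_STANDARD]
    dc = cost_s - cost_a
    dq = qaly_s - qaly_a
    inmb_draws = config.wtp * dq - dc
    ceac = np.array([(lam * dq - dc > 0.0).mean() for lam in lambdas])

    draws_df = pd.DataFrame(
        {
            "cost_accelerated": cost_a,
            "cost_standard": cost_s,
            "qaly_accelerated": qaly_a,
            "qaly_standard": qaly_s,
            "delta_cost": dc,
            "delta_qaly": dq,
            "inmb": inmb_draws,
        }
    )
    deterministic = None
    if include_deterministic:
        det = {
            arm: run_deterministic(params, arm, config, schedules) for arm in ARMS
        }
        deterministic = {
            arm: {"cost": det[arm].cost, "qalys": det[arm].qalys} for arm in ARMS
        }
    return CUAResult(
        arms={
            arm: {
                "cost_mean": float(c.mean()),
                "cost_sd": float(c.std(ddof=1)),
                "qaly_mean": float(q.mean()),
                "qaly_sd": float(q.std(ddof=1)),
            }
            for arm, (c, q) in per_arm.items()
        },
        delta_cost=float(dc.mean()),
        delta_qaly=float(dq.mean()),
        delta_cost_sd=float(dc.std(ddof=1)),
        delta_qaly_sd=float(dq.std(ddof=1)),
        icer=compute_icer(float(dc.mean()), float(dq.mean())),
        inmb=float(inmb_draws.mean()),
        inmb_cri=(
            float(np.percentile(inmb_draws, 2.5)),
            float(np.percentile(inmb_draws, 97.5)),
        ),
        wtp=config.wtp,
        ceac_lambdas=lambdas,
        ceac_probs=ceac,
        n_sims=n_sims,
        seed=seed,
        draws=draws_df,
        diagnostics={
            "n_renormalized_rows": n_renorm,
            "n_truncnorm_fallback_cycles": draws["n_fallback_cycles"],
            "calibration_factors": schedules.calibration_factors,
        },
        deterministic=deterministic,
    )


# ---------------------------------------------------------------------------
# one-way scenarios


def scenario_start_states(
    params: ModelParameters,
    krt_share_acc: float = 0.104,
    krt_share_std: float = 0.060,
    **psa_kwargs,
) -> CUAResult:
    """Trial-wide starting-state scenario.

    Replaces the Alberta KRT-dependence shares among 90-day survivors with
    the trial-wide values (default 10.4% accelerated / 6.0% standard),
    leaving survival and everything else unchanged.
    """
    for v in (krt_share_acc, krt_share_std):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"KRT share {v} outside [0, 1]")
    return run_psa(params.with_start_krt_shares(krt_share_acc, krt_share_std), **psa_kwargs)


def scenario_equal_costs(params: ModelParameters, **psa_kwargs) -> CUAResult:
    """Equal-monthly-cost scenario.

    Both arms receive the unweighted two-arm average of every month-4 and
    steady monthly cost parameter; one-time 0-90 day costs keep their
    arm-specific values.
    """
    return run_psa(params.with_pooled_monthly_costs(), **psa_kwargs)
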