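"""Model/results facade for the KRT-initiation cost-utility analysis.

`CostUtilityModel` bundles a :class:`~krtcua.params.ModelParameters` set with
run settings; :meth:`~CostUtilityModel.fit` runs the probabilistic
sensitivity analysis and returns a :class:`CUAResults` carrying estimates,
credible intervals, the acceptability curve and a ``summary()`` table.
:meth:`~CostUtilityModel.from_cohort` builds the parameter set from
patient-level data instead of published tables.

    >>> model = CostUtilityModel()          # published Alberta base case
    >>> res = model.fit(n_sims=5000, seed=1)
    >>> print(res.summary())
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Iterable

import numpy as np
import pandas as pd

from .estimation import (
    DEFAULT_STATE_SHARES,
    classify_states_frame,
    estimate_cost_params,
    estimate_transition_matrix,
    fit_beta_mom,
)
from .markov import ArmRun, ModelConfig, build_schedules, run_deterministic
from .params import (
    ArmCosts,
    BetaParam,
    CostParam,
    ModelParameters,
    StartParams,
    default_parameters,
)
from .psa import (
    CUAResult,
    run_psa,
    scenario_equal_costs,
    scenario_start_states,
)
from .reporting import RunManifest, render_results_table
from .states import ALIVE_STATES, ARM_STANDARD, ARMS, HealthState

__all__ = ["CostUtilityModel", "CUAResults"]

_SCENARIOS = ("base", "start-states", "equal-costs")


class CostUtilityModel:
    """Lifetime Markov cost-utility model of accelerated vs standard KRT
    initiation.

    Parameters
    ----------
    params : ModelParameters, optional
        Transition probabilities, utilities, costs and starting mixtures for
        both arms; defaults to the published Alberta base case.
    config : ModelConfig, optional
        Horizon, cycle length, discount rate, willingness-to-pay.
    """

    def __init__(self, params: ModelParameters | None = None, config: ModelConfig | None = None):
        self.params = params or default_parameters()
        self.config = config or ModelConfig()

    # -- construction from data ---------------------------------------------

    @classmethod
    def from_cohort(
        cls,
        cohort: pd.DataFrame | Iterable,
        base_params: ModelParameters | None = None,
        config: ModelConfig | None = None,
        state_shares: tuple[float, float, float] = DEFAULT_STATE_SHARES,
    ) -> "CostUtilityModel":
        """Estimate model parameters from a patient-level cohort table.

        Static transition probabilities, starting mixtures, monthly death
        means and period costs are estimated from the data; quantities the
        one-year window cannot identify (death-probability ranges, utility
        evidence when observations are scarce) fall back to ``base_params``
        (the published base case by default).
        """
        from .synthetic import records_to_frame

        df = cohort if isinstance(cohort, pd.DataFrame) else records_to_frame(list(cohort))
        base = base_params or default_parameters()
        config = config or ModelConfig()

        static_shared = dict(base.static_shared)
        static_by_arm = {k: dict(v) for k, v in base.static_by_arm.items()}
        death_means: dict[HealthState, list[float]] = {s: [] for s in ALIVE_STATES}
        start: dict[str, StartParams] = {}
        costs: dict[str, ArmCosts] = {}
        cost_table = estimate_cost_params(df, state_shares)

        for arm in ARMS:
            sub = df[df["arm"] == arm]
            if sub.empty:
                raise ValueError(f"cohort contains no patients in arm {arm!r}")
            est = estimate_transition_matrix(sub)
            est.require_estimable()
            n_rows = est.counts.sum(axis=1)
            for key in list(static_shared) + list(static_by_arm):
                frm, to = key
                p = float(est.matrix_monthly[frm, to])
                bp = _beta_from_proportion(p, n_rows[frm], base.static_shared.get(key) or base.static_by_arm[key][arm])
                if key in static_by_arm:
                    static_by_arm[key][arm] = bp
                elif arm == ARM_STANDARD:
                    # shared probabilities: pooled below would be better with
                    # counts, but arms are the same size; keep the last
                    # written value consistent by averaging.
                    prev = static_shared[key]
                    static_shared[key] = replace(bp, mean=(bp.mean + prev.mean) / 2.0)
                else:
                    static_shared[key] = bp
            for s in ALIVE_STATES:
                death_means[s].append(float(est.matrix_monthly[s, HealthState.DEAD]))

            s90 = classify_states_frame(sub, "90")
            alive = s90 != int(HealthState.DEAD)
            n_alive = int(alive.sum())
            krt = int((s90 == int(HealthState.KRT_DEPENDENT)).sum())
            nockd = int((s90 == int(HealthState.NO_CKD)).sum())
            non_krt = n_alive - krt
            start[arm] = StartParams(
                survival_90=n_alive / len(sub),
                krt_share_survivors=krt / n_alive if n_alive else 0.0,
                nockd_share_nonkrt=nockd / non_krt if non_krt else 0.5,
            )
            costs[arm] = _arm_costs_from_table(cost_table[arm])

        # Cap each death schedule's range so no row's off-diagonals can
        # exceed 1 once the estimated static probabilities are in place.
        static_row_sum = {s: 0.0 for s in ALIVE_STATES}
        for key, bp in static_shared.items():
            static_row_sum[key[0]] += bp.mean
        for key, d in static_by_arm.items():
            static_row_sum[key[0]] += max(v.mean for v in d.values())
        static_row_sum[HealthState.NO_CKD] += base.nockd_to_ckd_timedep.max_p

        death_timedep = {}
        for s in ALIVE_STATES:
            t = base.death_timedep[s]
            max_p = min(t.max_p, max(1.0 - static_row_sum[s] - 1e-9, t.min_p))
            mean = float(np.mean(death_means[s]))
            mean = min(max(mean, t.min_p), max_p)
            death_timedep[s] = replace(t, mean=mean, max_p=max_p)

        utilities = _utilities_from_cohort(df, base)
        params = ModelParameters(
            utilities=utilities,
            static_shared=static_shared,
            static_by_arm=static_by_arm,
            death_timedep=death_timedep,
            nockd_to_ckd_timedep=base.nockd_to_ckd_timedep,
            costs=costs,
            start=start,
        )
        return cls(params, config)

    # -- runs ----------------------------------------------------------------

    def run(self, arm: str) -> ArmRun:
        """Deterministic lifetime run of one arm at the parameter means."""
        return run_deterministic(self.params, arm, self.config)

    def fit(
        self,
        n_sims: int = 5000,
        seed: int | None = None,
        scenario: str = "base",
        **psa_kwargs,
    ) -> "CUAResults":
        """Run the PSA (optionally under a one-way scenario) and wrap results.

        ``scenario`` is ``"base"``, ``"start-states"`` (trial-wide KRT
        dependence at day 90) or ``"equal-costs"`` (pooled monthly costs).
        """
        if scenario not in _SCENARIOS:
            raise ValueError(f"unknown scenario {scenario!r}; expected one of {_SCENARIOS}")
        kwargs = dict(config=self.config, n_sims=n_sims, seed=seed, **psa_kwargs)
        if scenario == "start-states":
            raw = scenario_start_states(self.params, **kwargs)
        elif scenario == "equal-costs":
            raw = scenario_equal_costs(self.params, **kwargs)
        else:
            raw = run_psa(self.params, **kwargs)
        return CUAResults(self, raw, scenario)


def _beta_from_proportion(p: float, n: float, fallback: BetaParam) -> BetaParam:
    """Beta shapes for an estimated proportion via its binomial SE."""
    if n <= 1 or not 0.0 < p < 1.0:
        return replace(fallback, mean=min(max(p, 0.0), 1.0))
    se = math.sqrt(p * (1.0 - p) / n)
    try:
        spec = fit_beta_mom(p, se)
    except ValueError:
        return replace(fallback, mean=p)
    return BetaParam(p, spec.a, spec.b)


def _arm_costs_from_table(t: dict) -> ArmCosts:
    def cp(e: dict) -> CostParam:
        return CostParam(e["mean"], e["sd"])

    return ArmCosts(
        one_time=cp(t["cost_0_90"]),
        month4_total=cp(t["cost_91_120"]),
        monthly_total=cp(t["monthly_cost_121_365"]),
        month4_by_state={
            HealthState[n]: cp(e) for n, e in t["cost_91_120"]["by_state"].items()
        },
        monthly_by_state={
            HealthState[n]: cp(e) for n, e in t["monthly_cost_121_365"]["by_state"].items()
        },
    )


def _utilities_from_cohort(df: pd.DataFrame, base: ModelParameters) -> dict:
    """State utilities from observed EQ-5D-5L scores, pooled over both
    measurement days; published values fill in states with < 10 scores."""
    utilities = dict(base.utilities)
    obs: dict[HealthState, list[float]] = {s: [] for s in ALIVE_STATES}
    for when in ("90", "365"):
        states = classify_states_frame(df, when)
        u = pd.to_numeric(df[f"utility_{when}"], errors="coerce").to_numpy(float)
        for s in ALIVE_STATES:
            vals = u[(states == int(s)) & ~np.isnan(u)]
            obs[s].extend(vals.tolist())
    for s in ALIVE_STATES:
        vals = np.asarray(obs[s])
        if vals.size >= 10:
            mean, sd = float(vals.mean()), float(vals.std(ddof=1))
            try:
                spec = fit_beta_mom(mean, sd)
            except ValueError:
                continue
            utilities[s] = BetaParam(mean, spec.a, spec.b)
    return utilities


class CUAResults:
    """Fitted cost-utility results with statsmodels-style reporting.

    Wraps the raw :class:`~krtcua.psa.CUAResult` (available as ``.raw``);
    exposes the headline quantities as attributes and a ``summary()`` text
    table.
    """

    def __init__(self, model: CostUtilityModel, raw: CUAResult, scenario: str = "base"):
        self.model = model
        self.raw = raw
        self.scenario = scenario

    # headline quantities ----------------------------------------------------
    @property
    def delta_cost(self) -> float:
        return self.raw.delta_cost

    @property
    def delta_qaly(self) -> float:
        return self.raw.delta_qaly

    @property
    def icer(self) -> float | str:
        return self.raw.icer

    @property
    def inmb(self) -> float:
        return self.raw.inmb

    @property
    def inmb_cri(self) -> tuple[float, float]:
        return self.raw.inmb_cri

    @property
    def ceac_crossing(self) -> float | None:
        return self.raw.ceac_crossing

    @property
    def arms(self) -> dict:
        return self.raw.arms

    def ceac_frame(self) -> pd.DataFrame:
        return self.raw.ceac_frame()

    def table(self) -> pd.DataFrame:
        from .reporting import results_to_frame

        return results_to_frame({self.scenario: self.raw})

    def manifest(self) -> RunManifest:
        return RunManifest.from_result(self.raw, self.model.config)

    def render(self, path=None, fmt: str = "markdown") -> str:
        return render_results_table({self.scenario: self.raw}, path=path, fmt=fmt)

    def plot_ceac(self, ax=None):
        """Plot the acceptability curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.raw.ceac_lambdas, self.raw.ceac_probs)
        ax.axhline(0.5, ls="--", lw=0.8, color="grey")
        ax.set_xlabel("Willingness to pay, $/QALY")
        ax.set_ylabel("P(standard initiation cost-effective)")
        ax.set_ylim(0, 1)
        return ax

    def summary(self) -> str:
        r = self.raw

        def money(v: float) -> str:
            return f"{v:,.0f}".replace(",", " ")

        icer = r.icer.capitalize() if isinstance(r.icer, str) else money(r.icer)
        cross = r.ceac_crossing
        cross_s = f"${money(cross)}" if cross is not None else "no 0.5-crossing on grid"
        lines = [
            "Cost-Utility Analysis: standard vs accelerated KRT initiation",
            f"Scenario: {self.scenario}   PSA draws: {r.n_sims}   seed: {r.seed}",
            "=" * 70,
            f"{'Arm':<14}{'Cost, mean (SD), $':>26}{'QALYs, mean (SD)':>24}",
            "-" * 70,
        ]
        for arm in ARMS:
            a = r.arms[arm]
            lines.append(
                f"{arm:<14}"
                f"{money(a['cost_mean']) + ' (' + money(a['cost_sd']) + ')':>26}"
                f"{a['qaly_mean']:>15.2f} ({a['qaly_sd']:.2f})"
            )
        lines += [
            "-" * 70,
            f"Incremental cost (standard - accelerated): ${money(r.delta_cost)}"
            f" (SD {money(r.delta_cost_sd)})",
            f"Incremental QALYs: {r.delta_qaly:.2f} (SD {r.delta_qaly_sd:.2f})",
            f"ICER: {icer}" + ("" if isinstance(r.icer, str) else " $/QALY"),
            f"INMB at ${money(r.wtp)}/QALY: ${money(r.inmb)} "
            f"(95% CrI {money(r.inmb_cri[0])} to {money(r.inmb_cri[1])})",
            f"CEAC crosses P = 0.5 at: {cross_s}",
            "=" * 70,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<CUAResults scenario={self.scenario!r} n_sims={self.raw.n_sims}>"
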