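"""Model parameters: utilities, transition probabilities, costs, start states.

`ModelParameters` bundles everything the Markov engine and the probabilistic
sensitivity analysis need, per arm where the evidence is arm-specific:

* state utilities with beta shape parameters (deterministic runs use the
  recorded mean, PSA samples from the shapes);
* static monthly transition probabilities among the alive states, likewise
  with beta shapes — only CKD -> no-CKD recovery differs by arm;
* time-dependent monthly probabilities (the three state-specific death
  probabilities and no-CKD -> CKD progression) summarized as mean + range,
  from which a calibrated per-cycle schedule is built;
* period costs (one-time 0-90 day, month-4, steady monthly) with mean/SD for
  gamma sampling, decomposed across alive states;
* the day-90 starting mixture per arm (90-day survival, KRT dependence among
  survivors, and the no-CKD share of the remaining survivors).

`default_parameters()` returns the published Alberta base case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .states import (
    ARM_ACCELERATED,
    ARM_STANDARD,
    ARMS,
    ALIVE_STATES,
    N_STATES,
    HealthState,
    check_arm,
)

__all__ = [
    "BetaParam",
    "CostParam",
    "TimeDepParam",
    "ArmCosts",
    "StartParams",
    "ModelParameters",
    "default_parameters",
    "starting_distribution",
]


@dataclass(frozen=True)
class BetaParam:
    """A probability or utility: point value plus beta(a, b) for PSA.

    ``mean`` is the value used deterministically; ``a``/``b`` are the shape
    parameters sampled in PSA.  The two need not be perfectly consistent
    (published tables sometimes round them apart); the implied mean is
    available as :attr:`implied_mean`.
    """

    mean: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean <= 1.0:
            raise ValueError(f"mean {self.mean} outside [0, 1]")
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"beta shapes must be positive: ({self.a}, {self.b})")

    @property
    def implied_mean(self) -> float:
        return self.a / (self.a + self.b)


@dataclass(frozen=True)
class CostParam:
    """A cost in 2024 CAD, mean and SD; PSA fits a gamma by moments."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.mean < 0 or self.sd < 0:
            raise ValueError(f"cost mean/SD must be nonnegative: {self}")


@dataclass(frozen=True)
class TimeDepParam:
    """A time-dependent monthly probability summarized as mean and range."""

    mean: float
    min_p: float
    max_p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_p <= self.max_p <= 1.0:
            raise ValueError(f"invalid range [{self.min_p}, {self.max_p}]")
        if not self.min_p <= self.mean <= self.max_p:
            raise ValueError(
                f"mean {self.mean} outside range [{self.min_p}, {self.max_p}]"
            )


@dataclass(frozen=True)
class ArmCosts:
    """Period costs for one arm under the model's cost periodization.

    ``one_time`` covers index admission to day 90 and is booked once at model
    entry; ``month4_*`` applies only to the first model cycle (days 91-120,
    when post-ICU costs are still elevated); ``monthly_*`` is the steady
    monthly cost from day 121 on, extrapolated over the remaining lifetime.
    ``*_by_state`` decompose the period totals across the alive states.
    """

    one_time: CostParam
    month4_total: CostParam
    monthly_total: CostParam
    month4_by_state: dict[HealthState, CostParam]
    monthly_by_state: dict[HealthState, CostParam]


@dataclass(frozen=True)
class StartParams:
    """Day-90 starting mixture for one arm."""

    survival_90: float
    krt_share_survivors: float
    nockd_share_nonkrt: float = 0.5

    def __post_init__(self) -> None:
        for name in ("survival_90", "krt_share_survivors", "nockd_share_nonkrt"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")


def starting_distribution(start: StartParams, include_decedents: bool = True) -> np.ndarray:
    """Occupancy over (no CKD, CKD, KRT, dead) at model entry (day 90).

    With ``include_decedents`` (the default) the dead fraction
    1 - survival_90 enters the starting vector, so model outputs are
    per-randomized-patient means rather than per-survivor means.
    """
    alive = start.survival_90 if include_decedents else 1.0
    krt = alive * start.krt_share_survivors
    nonkrt = alive - krt
    vec = np.array(
        [
            nonkrt * start.nockd_share_nonkrt,
            nonkrt * (1.0 - start.nockd_share_nonkrt),
            krt,
            1.0 - alive,
        ]
    )
    assert abs(vec.sum() - 1.0) < 1e-12
    return vec


# Keys for static transitions, in (from, to) state pairs.
StaticKey = tuple[HealthState, HealthState]


@dataclass
class ModelParameters:
    """Everything the Markov engine and PSA consume, for both arms."""

    utilities: dict[HealthState, BetaParam]
    static_shared: dict[StaticKey, BetaParam]
    static_by_arm: dict[StaticKey, dict[str, BetaParam]]
    death_timedep: dict[HealthState, TimeDepParam]
    nockd_to_ckd_timedep: TimeDepParam
    costs: dict[str, ArmCosts]
    start: dict[str, StartParams]

    def static_transition(self, frm: HealthState, to: HealthState, arm: str) -> BetaParam:
        """Resolve a static transition probability, arm-specific if needed."""
        check_arm(arm)
        key = (frm, to)
        if key in self.static_by_arm:
            return self.static_by_arm[key][arm]
        return self.static_shared[key]

    def static_keys(self) -> list[StaticKey]:
        return list(self.static_shared) + list(self.static_by_arm)

    # ---- scenario helpers -------------------------------------------------

    def with_start_krt_shares(self, acc: float, std: float) -> "ModelParameters":
        """Replace only the KRT share among survivors in each arm's start."""
        new_start = {
            ARM_ACCELERATED: replace(self.start[ARM_ACCELERATED], krt_share_survivors=acc),
            ARM_STANDARD: replace(self.start[ARM_STANDARD], krt_share_survivors=std),
        }
        return replace(self, start=new_start)

    def with_pooled_monthly_costs(self) -> "ModelParameters":
        """Equal-monthly-cost scenario: both arms get the unweighted two-arm
        average of every month-4 and steady monthly cost parameter; the
        one-time 0-90 day costs are untouched."""

        def pool(a: CostParam, b: CostParam) -> CostParam:
            return CostParam((a.mean + b.mean) / 2.0, (a.sd + b.sd) / 2.0)

        ca, cs = self.costs[ARM_ACCELERATED], self.costs[ARM_STANDARD]
        pooled_m4_total = pool(ca.month4_total, cs.month4_total)
        pooled_mo_total = pool(ca.monthly_total, cs.monthly_total)
        pooled_m4 = {s: pool(ca.month4_by_state[s], cs.month4_by_state[s]) for s in ALIVE_STATES}
        pooled_mo = {s: pool(ca.monthly_by_state[s], cs.monthly_by_state[s]) for s in ALIVE_STATES}
        new_costs = {
            arm: ArmCosts(
                one_time=self.costs[arm].one_time,
                month4_total=pooled_m4_total,
                monthly_total=pooled_mo_total,
                month4_by_state=dict(pooled_m4),
                monthly_by_state=dict(pooled_mo),
            )
            for arm in ARMS
        }
        return replace(self, costs=new_costs)

    # ---- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        def beta(p: BetaParam) -> dict:
            return {"mean": float(p.mean), "alpha": float(p.a), "beta": float(p.b)}

        def cost(c: CostParam) -> dict:
            return {"mean": float(c.mean), "sd": float(c.sd)}

        def timedep(t: TimeDepParam) -> dict:
            return {"mean": float(t.mean), "min": float(t.min_p), "max": float(t.max_p)}

        return {
            "utilities": {s.name: beta(self.utilities[s]) for s in ALIVE_STATES},
            "static_transitions": {
                "shared": {
                    f"{k[0].name}->{k[1].name}": beta(v)
                    for k, v in self.static_shared.items()
                },
                "by_arm": {
                    f"{k[0].name}->{k[1].name}": {a: beta(v) for a, v in d.items()}
                    for k, d in self.static_by_arm.items()
                },
            },
            "time_dependent": {
                "death": {s.name: timedep(self.death_timedep[s]) for s in ALIVE_STATES},
                "NO_CKD->CKD_NO_KRT": timedep(self.nockd_to_ckd_timedep),
            },
            "costs": {
                arm: {
                    "one_time_0_90": cost(c.one_time),
                    "month4_total": cost(c.month4_total),
                    "monthly_total": cost(c.monthly_total),
                    "month4_by_state": {s.name: cost(c.month4_by_state[s]) for s in ALIVE_STATES},
                    "monthly_by_state": {s.name: cost(c.monthly_by_state[s]) for s in ALIVE_STATES},
                }
                for arm, c in self.costs.items()
            },
            "start": {
                arm: {
                    "survival_90": float(s.survival_90),
                    "krt_share_survivors": float(s.krt_share_survivors),
                    "nockd_share_nonkrt": float(s.nockd_share_nonkrt),
                }
                for arm, s in self.start.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        def beta(e: dict) -> BetaParam:
            return BetaParam(e["mean"], e["alpha"], e["beta"])

        def cost(e: dict) -> CostParam:
            return CostParam(e["mean"], e["sd"])

        def timedep(e: dict) -> TimeDepParam:
            return TimeDepParam(e["mean"], e["min"], e["max"])

        def key(s: str) -> StaticKey:
            a, b = s.split("->")
            return (HealthState[a], HealthState[b])

        st = d["static_transitions"]
        return cls(
            utilities={HealthState[n]: beta(e) for n, e in d["utilities"].items()},
            static_shared={key(n): beta(e) for n, e in st["shared"].items()},
            static_by_arm={
                key(n): {a: beta(e) for a, e in arms.items()}
                for n, arms in st["by_arm"].items()
            },
            death_timedep={
                HealthState[n]: timedep(e) for n, e in d["time_dependent"]["death"].items()
            },
            nockd_to_ckd_timedep=timedep(d["time_dependent"]["NO_CKD->CKD_NO_KRT"]),
            costs={
                arm: ArmCosts(
                    one_time=cost(e["one_time_0_90"]),
                    month4_total=cost(e["month4_total"]),
                    monthly_total=cost(e["monthly_total"]),
                    month4_by_state={
                        HealthState[n]: cost(c) for n, c in e["month4_by_state"].items()
                    },
                    monthly_by_state={
                        HealthState[n]: cost(c) for n, c in e["monthly_by_state"].items()
                    },
                )
                for arm, e in d["costs"].items()
            },
            start={
                arm: StartParams(
                    e["survival_90"], e["krt_share_survivors"], e["nockd_share_nonkrt"]
                )
                for arm, e in d["start"].items()
            },
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(d, sort_keys=False))
        else:
            path.write_text(json.dumps(d, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ModelParameters":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(d)


def default_parameters() -> ModelParameters:
    """The published Alberta base case (costs in 2024 CAD).

    Utilities come from EQ-5D-5L literature values for incident CKD; static
    monthly transition probabilities and the time-dependent summaries were
    estimated from the 146-patient Alberta trial cohort linked to
    administrative data; costs are the linked health-system costs by period.
    """
    S = HealthState
    return ModelParameters(
        utilities={
            S.NO_CKD: BetaParam(0.85, 80.00, 14.40),
            S.CKD_NO_KRT: BetaParam(0.74, 49.90, 18.00),
            S.KRT_DEPENDENT: BetaParam(0.60, 44.80, 30.00),
        },
        static_shared={
            (S.NO_CKD, S.KRT_DEPENDENT): BetaParam(0.001, 0.059, 56.413),
            (S.CKD_NO_KRT, S.KRT_DEPENDENT): BetaParam(0.016, 0.064, 4.265),
            (S.KRT_DEPENDENT, S.NO_CKD): BetaParam(0.073, 0.359, 4.379),
            (S.KRT_DEPENDENT, S.CKD_NO_KRT): BetaParam(0.063, 0.036, 0.521),
        },
        static_by_arm={
            (S.CKD_NO_KRT, S.NO_CKD): {
                ARM_STANDARD: BetaParam(0.139, 0.396, 2.479),
                ARM_ACCELERATED: BetaParam(0.063, 0.110, 1.659),
            },
        },
        death_timedep={
            S.NO_CKD: TimeDepParam(0.022, 0.001, 0.990),
            S.CKD_NO_KRT: TimeDepParam(0.030, 0.003, 0.990),
            S.KRT_DEPENDENT: TimeDepParam(0.033, 0.005, 0.990),
        },
        nockd_to_ckd_timedep=TimeDepParam(0.001, 0.000, 0.017),
        costs={
            ARM_ACCELERATED: ArmCosts(
                one_time=CostParam(182_626, 175_710),
                month4_total=CostParam(28_486, 126_302),
                monthly_total=CostParam(3_293, 4_335),
                month4_by_state={
                    S.KRT_DEPENDENT: CostParam(20_299, 90_000),
                    S.CKD_NO_KRT: CostParam(4_709, 20_880),
                    S.NO_CKD: CostParam(3_478, 15_423),
                },
                monthly_by_state={
                    S.KRT_DEPENDENT: CostParam(2_346, 3_089),
                    S.CKD_NO_KRT: CostParam(544, 717),
                    S.NO_CKD: CostParam(402, 529),
                },
            ),
            ARM_STANDARD: ArmCosts(
                one_time=CostParam(161_601, 104_048),
                month4_total=CostParam(9_141, 25_820),
                monthly_total=CostParam(5_558, 8_280),
                month4_by_state={
                    S.KRT_DEPENDENT: CostParam(6_514, 18_398),
                    S.CKD_NO_KRT: CostParam(1_511, 4_268),
                    S.NO_CKD: CostParam(1_116, 3_153),
                },
                monthly_by_state={
                    S.KRT_DEPENDENT: CostParam(3_960, 5_900),
                    S.CKD_NO_KRT: CostParam(919, 1_369),
                    S.NO_CKD: CostParam(679, 1_011),
                },
            ),
        },
        start={
            ARM_ACCELERATED: StartParams(0.685, 0.021, 0.5),
            ARM_STANDARD: StartParams(0.781, 0.098, 0.5),
        },
    )
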