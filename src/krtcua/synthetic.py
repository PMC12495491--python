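"""Synthetic trial-cohort generator.

The study's patient-level inputs are confidential linked administrative
records, so this module generates cohorts with the same statistical
structure: per-arm 90-day survival, dialysis (KRT) dependence among
survivors, an eGFR split of the remaining survivors into no-CKD vs CKD,
gamma-distributed period costs, beta-distributed EQ-5D-5L utilities, and a
day-90 -> day-365 state evolution driven by configured monthly transition
probabilities (9 cycles), so that downstream estimation can be validated by
parameter recovery.

All randomness flows through one `numpy.random.Generator` seeded from the
config; identical configs give byte-identical CSV output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .states import ALIVE_STATES, ARMS, N_STATES, HealthState, check_arm

__all__ = [
    "CohortConfig",
    "PatientRecord",
    "generate_cohort",
    "generate_cohort_frame",
    "write_cohort",
    "read_cohort",
    "records_to_frame",
    "frame_to_records",
    "default_cohort_config",
    "CohortParseError",
]

#: Monthly cycles simulated between day 90 and day 365.
N_EVOLUTION_CYCLES = 9

#: Column order of the cohort CSV (one row per patient).
COLUMNS = [
    "patient_id",
    "arm",
    "age",
    "alive_90",
    "alive_365",
    "egfr_90",
    "egfr_365",
    "krt_90",
    "krt_365",
    "cost_0_90",
    "cost_91_120",
    "monthly_cost_121_365",
    "utility_90",
    "utility_365",
]

_COST_PERIODS = ("cost_0_90", "cost_91_120", "monthly_cost_121_365")


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic trial participant.

    ``None`` encodes "absent": day-365 fields are absent for 90-day
    decedents, eGFR is absent for the dead and for KRT-dependent patients'
    classification purposes it is still drawn (dialysis dominates it), and
    post-90-day costs are absent for 90-day decedents.
    """

    patient_id: str
    arm: str
    age: float
    alive_90: bool
    alive_365: bool
    egfr_90: float | None
    egfr_365: float | None
    krt_90: bool | None
    krt_365: bool | None
    cost_0_90: float
    cost_91_120: float | None
    monthly_cost_121_365: float | None
    utility_90: float | None
    utility_365: float | None

    def __post_init__(self) -> None:
        check_arm(self.arm)
        if not self.alive_90:
            if self.alive_365:
                raise ValueError(f"{self.patient_id}: dead at 90 d but alive at 365 d")
            for name in ("egfr_365", "krt_365", "utility_365", "cost_91_120",
                         "monthly_cost_121_365", "egfr_90", "krt_90", "utility_90"):
                if getattr(self, name) is not None:
                    raise ValueError(
                        f"{self.patient_id}: field {name} must be absent for a "
                        "90-day decedent"
                    )
        elif not self.alive_365:
            for name in ("egfr_365", "krt_365", "utility_365"):
                if getattr(self, name) is not None:
                    raise ValueError(
                        f"{self.patient_id}: day-365 field {name} must be absent "
                        "for a decedent"
                    )
        for name in _COST_PERIODS:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{self.patient_id}: negative cost in {name}")
        for name in ("utility_90", "utility_365"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.patient_id}: {name} outside [0, 1]")


def _check_prob(name: str, value: float) -> float:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} = {value} is not a probability")
    return float(value)


@dataclass
class CohortConfig:
    """Targets the generator must hit (per arm where arm-specific).

    ``transition_probs_90_to_365`` maps arm -> a 4x4 *monthly* row-stochastic
    matrix applied for 9 cycles to evolve day-90 states to day 365.
    ``cost_params_by_arm`` maps arm -> {period: (mean, sd)} for the three
    cost periods; costs are drawn from method-of-moments gamma fits (a
    zero SD yields the constant).  ``state_cost_shares``, if given as
    (KRT, CKD, no-CKD) shares, tilts post-90-day costs by day-90 state so
    the aggregate cost decomposition matches those shares while preserving
    the configured overall means.
    """

    n_per_arm: int
    survival90_by_arm: Mapping[str, float]
    krt_dep_among_survivors_by_arm: Mapping[str, float]
    cost_params_by_arm: Mapping[str, Mapping[str, tuple[float, float]]]
    utility_means_by_state: Mapping[HealthState, float]
    transition_probs_90_to_365: Mapping[str, np.ndarray]
    nockd_share_among_nonkrt_survivors: float = 0.5
    utility_sds_by_state: Mapping[HealthState, float] | None = None
    state_cost_shares: tuple[float, float, float] | None = None
    age_mean: float = 61.0
    age_sd: float = 13.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 0:
            raise ValueError(f"n_per_arm must be >= 0, got {self.n_per_arm}")
        for arm in ARMS:
            _check_prob(f"survival90[{arm}]", self.survival90_by_arm[arm])
            _check_prob(
                f"krt_dep_among_survivors[{arm}]",
                self.krt_dep_among_survivors_by_arm[arm],
            )
            mat = np.asarray(self.transition_probs_90_to_365[arm], dtype=float)
            if mat.shape != (N_STATES, N_STATES):
                raise ValueError(f"transition matrix for {arm} must be 4x4")
            if (mat < 0).any() or (mat > 1).any():
                raise ValueError(f"transition matrix for {arm} has entries outside [0, 1]")
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"transition matrix for {arm} is not row-stochastic")
            for period in _COST_PERIODS:
                mean, sd = self.cost_params_by_arm[arm][period]
                if mean < 0 or sd < 0:
                    raise ValueError(f"cost {period}[{arm}] mean/SD must be >= 0")
        _check_prob("nockd_share_among_nonkrt_survivors", self.nockd_share_among_nonkrt_survivors)
        for s in ALIVE_STATES:
            _check_prob(f"utility mean[{s.name}]", self.utility_means_by_state[s])
        if self.state_cost_shares is not None:
            shares = np.asarray(self.state_cost_shares, dtype=float)
            if shares.shape != (3,) or (shares < 0).any() or abs(shares.sum() - 1) > 1e-6:
                raise ValueError("state_cost_shares must be 3 nonnegative shares summing to 1")

    def utility_sd(self, state: HealthState) -> float:
        if self.utility_sds_by_state is not None:
            return float(self.utility_sds_by_state[state])
        return 0.05


# ---------------------------------------------------------------------------
# sampling helpers


def _gamma_sample(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Method-of-moments gamma draws; SD = 0 emits the constant."""
    if size == 0:
        return np.empty(0)
    if sd == 0.0:
        return np.full(size, mean, dtype=float)
    if mean == 0.0:
        return np.zeros(size)
    k = (mean / sd) ** 2
    theta = sd * sd / mean
    return rng.gamma(k, theta, size)


def _beta_sample(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    if size == 0:
        return np.empty(0)
    if sd == 0.0:
        return np.full(size, mean)
    var = sd * sd
    bound = mean * (1.0 - mean)
    if var >= bound:
        raise ValueError(f"infeasible beta moments (mean={mean}, sd={sd})")
    nu = bound / var - 1.0
    return rng.beta(mean * nu, (1.0 - mean) * nu, size)


def _egfr_sample(rng: np.random.Generator, states: np.ndarray) -> np.ndarray:
    """eGFR consistent with each alive state's classification.

    Only the >= 60 / < 60 split matters downstream, so the shapes are simple
    truncated normals: no-CKD ~ N(75, 12) truncated to [60, inf), CKD
    ~ N(45, 12) truncated to [5, 60).  KRT-dependent patients get a CKD-range
    value (dialysis dominates classification); the dead get NaN.
    """
    out = np.full(states.shape, np.nan)
    hi = states == HealthState.NO_CKD
    lo = (states == HealthState.CKD_NO_KRT) | (states == HealthState.KRT_DEPENDENT)
    if hi.any():
        a, b = (60.0 - 75.0) / 12.0, np.inf
        out[hi] = stats.truncnorm.rvs(a, b, loc=75.0, scale=12.0, size=int(hi.sum()), random_state=rng)
    if lo.any():
        a, b = (5.0 - 45.0) / 12.0, (60.0 - 45.0) / 12.0
        out[lo] = stats.truncnorm.rvs(a, b, loc=45.0, scale=12.0, size=int(lo.sum()), random_state=rng)
    return out


def _evolve_states(
    rng: np.random.Generator, states: np.ndarray, monthly: np.ndarray, n_cycles: int
) -> np.ndarray:
    """Evolve each patient's state through ``n_cycles`` multinomial steps."""
    cum = monthly.cumsum(axis=1)
    out = states.copy()
    for _ in range(n_cycles):
        u = rng.random(out.shape[0])
        out = (u[:, None] > cum[out]).sum(axis=1)
    return out


# ---------------------------------------------------------------------------
# generation


def generate_cohort_frame(config: CohortConfig) -> pd.DataFrame:
    """Generate the cohort as a DataFrame (columns = PatientRecord fields)."""
    rng = np.random.default_rng(config.seed)
    frames = []
    for arm in ARMS:
        frames.append(_generate_arm(rng, arm, config))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=COLUMNS)
    return df[COLUMNS]


def _generate_arm(rng: np.random.Generator, arm: str, config: CohortConfig) -> pd.DataFrame:
    n = config.n_per_arm
    surv = config.survival90_by_arm[arm]
    krt_share = config.krt_dep_among_survivors_by_arm[arm]
    nockd_share = config.nockd_share_among_nonkrt_survivors

    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18.0, None)
    alive_90 = rng.random(n) < surv

    # Day-90 state assignment.
    s90 = np.full(n, int(HealthState.DEAD))
    n_alive = int(alive_90.sum())
    krt = rng.random(n_alive) < krt_share
    nockd = rng.random(n_alive) < nockd_share
    alive_states = np.where(
        krt,
        int(HealthState.KRT_DEPENDENT),
        np.where(nockd, int(HealthState.NO_CKD), int(HealthState.CKD_NO_KRT)),
    )
    s90[alive_90] = alive_states

    egfr_90 = _egfr_sample(rng, s90)

    # Evolve day-90 -> day-365 with the configured monthly matrix.
    monthly = np.asarray(config.transition_probs_90_to_365[arm], dtype=float)
    s365 = _evolve_states(rng, s90, monthly, N_EVOLUTION_CYCLES)
    alive_365 = s365 != int(HealthState.DEAD)
    egfr_365 = _egfr_sample(rng, np.where(alive_365, s365, int(HealthState.DEAD)))

    # Costs: 0-90 d for everyone; later periods only for 90-day survivors.
    cp = config.cost_params_by_arm[arm]
    cost_0_90 = _gamma_sample(rng, *cp["cost_0_90"], n)
    cost_91_120 = np.full(n, np.nan)
    monthly_cost = np.full(n, np.nan)
    mult = _state_cost_multipliers(config, surv, krt_share, nockd_share)
    for col, (mean, sd) in (("cost_91_120", cp["cost_91_120"]),
                            ("monthly_cost_121_365", cp["monthly_cost_121_365"])):
        target = cost_91_120 if col == "cost_91_120" else monthly_cost
        if mult is None:
            target[alive_90] = _gamma_sample(rng, mean, sd, n_alive)
        else:
            for s in ALIVE_STATES:
                mask = s90 == int(s)
                target[mask] = _gamma_sample(
                    rng, mean * mult[s], sd * mult[s], int(mask.sum())
                )

    # Utilities by concurrent state.
    utility_90 = np.full(n, np.nan)
    utility_365 = np.full(n, np.nan)
    for s in ALIVE_STATES:
        m = config.utility_means_by_state[s]
        sd = config.utility_sd(s)
        mask90 = s90 == int(s)
        utility_90[mask90] = _beta_sample(rng, m, sd, int(mask90.sum()))
        mask365 = s365 == int(s)
        utility_365[mask365] = _beta_sample(rng, m, sd, int(mask365.sum()))

    dead90 = ~alive_90
    egfr_90[dead90] = np.nan

    krt_90 = np.where(alive_90, (s90 == int(HealthState.KRT_DEPENDENT)).astype(float), np.nan)
    krt_365 = np.where(alive_365, (s365 == int(HealthState.KRT_DEPENDENT)).astype(float), np.nan)

    prefix = "A" if arm == ARMS[0] else "S"
    ids = [f"{prefix}{i:06d}" for i in range(n)]
    return pd.DataFrame(
        {
            "patient_id": ids,
            "arm": arm,
            "age": age,
            "alive_90": alive_90,
            "alive_365": alive_365,
            "egfr_90": egfr_90,
            "egfr_365": egfr_365,
            "krt_90": krt_90,
            "krt_365": krt_365,
            "cost_0_90": cost_0_90,
            "cost_91_120": cost_91_120,
            "monthly_cost_121_365": monthly_cost,
            "utility_90": utility_90,
            "utility_365": utility_365,
        }
    )


def _state_cost_multipliers(
    config: CohortConfig, surv: float, krt_share: float, nockd_share: float
) -> dict[HealthState, float] | None:
    """Per-state cost multipliers hitting the target cost-share decomposition.

    If state s holds expected occupancy fraction p_s of 90-day survivors and
    must carry share w_s of the aggregate cost, its mean must be scaled by
    w_s / p_s; the overall survivor mean is then preserved in expectation.
    """
    if config.state_cost_shares is None:
        return None
    w_krt, w_ckd, w_nockd = config.state_cost_shares
    p_krt = krt_share
    p_nockd = (1.0 - krt_share) * nockd_share
    p_ckd = (1.0 - krt_share) * (1.0 - nockd_share)
    occ = {
        HealthState.KRT_DEPENDENT: p_krt,
        HealthState.CKD_NO_KRT: p_ckd,
        HealthState.NO_CKD: p_nockd,
    }
    shares = {
        HealthState.KRT_DEPENDENT: w_krt,
        HealthState.CKD_NO_KRT: w_ckd,
        HealthState.NO_CKD: w_nockd,
    }
    out = {}
    for s, p in occ.items():
        if shares[s] > 0 and p == 0:
            raise ValueError(
                f"state {s.name} must carry cost share {shares[s]} but has zero "
                "expected occupancy"
            )
        out[s] = shares[s] / p if p > 0 else 0.0
    return out


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Generate the cohort as a list of validated PatientRecords."""
    return frame_to_records(generate_cohort_frame(config))


# ---------------------------------------------------------------------------
# CSV round trip


class CohortParseError(ValueError):
    """A cohort CSV violated the record invariants."""


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    if not records:
        return pd.DataFrame(columns=COLUMNS)
    df = pd.DataFrame([asdict(r) for r in records])
    return df[COLUMNS]


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        d = dict(zip(df.columns, row))
        try:
            records.append(
                PatientRecord(
                    patient_id=str(d["patient_id"]),
                    arm=str(d["arm"]),
                    age=float(d["age"]),
                    alive_90=_req_bool(d["alive_90"]),
                    alive_365=_req_bool(d["alive_365"]),
                    egfr_90=_opt(d["egfr_90"]),
                    egfr_365=_opt(d["egfr_365"]),
                    krt_90=_opt_bool(d["krt_90"]),
                    krt_365=_opt_bool(d["krt_365"]),
                    cost_0_90=float(d["cost_0_90"]),
                    cost_91_120=_opt(d["cost_91_120"]),
                    monthly_cost_121_365=_opt(d["monthly_cost_121_365"]),
                    utility_90=_opt(d["utility_90"]),
                    utility_365=_opt(d["utility_365"]),
                )
            )
        except (ValueError, KeyError) as exc:
            raise CohortParseError(f"row {i}: {exc}") from exc
    return records


def _opt(v) -> float | None:
    if v is None:
        return None
    v = float(v)
    return None if math.isnan(v) else v


def _opt_bool(v) -> bool | None:
    v = _opt(float(v) if isinstance(v, (bool, np.bool_)) else v)
    return None if v is None else bool(v)


def _req_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    return bool(float(v))


def write_cohort(records, path: str | Path) -> None:
    """Write a cohort (records or DataFrame) to CSV; absent values are empty."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    out = df.copy()
    for col in ("alive_90", "alive_365", "krt_90", "krt_365"):
        # bool flags as 0/1; absent flags stay empty
        out[col] = out[col].map(
            lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v)) else int(bool(v))
        )
    for col in ("age", *_COST_PERIODS, "egfr_90", "egfr_365", "utility_90", "utility_365"):
        # repr round-trips float64 exactly; empty cell encodes "absent"
        out[col] = out[col].map(
            lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v)) else repr(float(v))
        )
    out.to_csv(path, index=False)


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read a cohort CSV, validating every record invariant.

    Raises :class:`CohortParseError` naming the offending row and column on
    malformed input (e.g. negative costs).
    """
    try:
        df = pd.read_csv(
            path, dtype={"patient_id": str, "arm": str}, float_precision="round_trip"
        )
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise CohortParseError(f"cannot parse {path}: {exc}") from exc
    if df.empty:
        return []
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise CohortParseError(f"missing columns: {sorted(missing)}")
    return frame_to_records(df)


def default_cohort_config(n_per_arm: int = 1000, seed: int = 0, **overrides) -> CohortConfig:
    """A config matching the published Alberta targets.

    Survival and KRT-dependence targets come from the trial results; the
    monthly transition matrices combine the static transition means with the
    mean time-dependent death/progression probabilities; costs and utilities
    use the published period means/SDs and state utilities.
    """
    from .params import default_parameters
    from .markov import monthly_matrix_from_means

    p = default_parameters()
    S = HealthState
    cfg = dict(
        n_per_arm=n_per_arm,
        survival90_by_arm={arm: p.start[arm].survival_90 for arm in ARMS},
        krt_dep_among_survivors_by_arm={
            arm: p.start[arm].krt_share_survivors for arm in ARMS
        },
        cost_params_by_arm={
            arm: {
                "cost_0_90": (p.costs[arm].one_time.mean, p.costs[arm].one_time.sd),
                "cost_91_120": (p.costs[arm].month4_total.mean, p.costs[arm].month4_total.sd),
                "monthly_cost_121_365": (
                    p.costs[arm].monthly_total.mean,
                    p.costs[arm].monthly_total.sd,
                ),
            }
            for arm in ARMS
        },
        utility_means_by_state={s: p.utilities[s].mean for s in ALIVE_STATES},
        transition_probs_90_to_365={
            arm: monthly_matrix_from_means(p, arm) for arm in ARMS
        },
        seed=seed,
    )
    cfg.update(overrides)
    return CohortConfig(**cfg)
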