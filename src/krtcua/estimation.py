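"""Parameter estimation from patient-level data.

Turns a cohort table (one row per patient: arm, vital status and eGFR at days
90 and 365, KRT status, period costs) into the quantities the Markov model
consumes: health-state classification, the 4x4 day-90 -> day-365 transition
matrix with its monthly adjustment, period/state cost summaries, and
method-of-moments beta and gamma distribution fits used by the probabilistic
sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .states import ALIVE_STATES, ARMS, N_STATES, HealthState

__all__ = [
    "DistributionSpec",
    "TransitionEstimate",
    "classify_state",
    "classify_states_frame",
    "period_to_monthly",
    "fit_beta_mom",
    "fit_gamma_mom",
    "estimate_transition_matrix",
    "estimate_cost_params",
    "compute_state_shares",
    "EGFR_CKD_THRESHOLD",
    "N_CYCLES_90_TO_365",
]

#: eGFR boundary (mL/min/1.73 m2) between "no CKD" and "CKD, not KRT
#: dependent"; the boundary value itself classifies as no CKD (>= 60).
EGFR_CKD_THRESHOLD = 60.0

#: Monthly cycles between day 90 and day 365 (9 ~30-day months).
N_CYCLES_90_TO_365 = 9


@dataclass(frozen=True)
class DistributionSpec:
    """A beta or gamma distribution with both shapes and moments recorded.

    For a beta, ``a``/``b`` are the alpha/beta shape parameters; for a gamma,
    ``a`` is the shape k and ``b`` the scale theta.  ``mean`` and ``sd`` are
    the implied (or fitted) first two moments and must stay consistent with
    the shapes.
    """

    family: Literal["beta", "gamma"]
    a: float
    b: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma"):
            raise ValueError(f"unknown family {self.family!r}")
        if not (self.a > 0 and self.b > 0):
            raise ValueError(
                f"{self.family} shape parameters must be positive, got "
                f"({self.a}, {self.b})"
            )
        if self.family == "beta":
            implied = self.a / (self.a + self.b)
        else:
            implied = self.a * self.b
        if abs(implied - self.mean) > 1e-9 * max(1.0, abs(implied)):
            raise ValueError(
                f"recorded mean {self.mean} inconsistent with shapes "
                f"({self.a}, {self.b}) implying {implied}"
            )

    @classmethod
    def beta_from_shapes(cls, a: float, b: float) -> "DistributionSpec":
        """Build a beta spec from its shape parameters (forward moment map)."""
        if not (a > 0 and b > 0):
            raise ValueError("beta shapes must be positive")
        mean = a / (a + b)
        var = a * b / ((a + b) ** 2 * (a + b + 1.0))
        return cls("beta", a, b, mean, math.sqrt(var))

    @classmethod
    def gamma_from_shapes(cls, k: float, theta: float) -> "DistributionSpec":
        """Build a gamma spec from shape/scale (forward moment map)."""
        if not (k > 0 and theta > 0):
            raise ValueError("gamma shape/scale must be positive")
        return cls("gamma", k, theta, k * theta, math.sqrt(k) * theta)


def fit_beta_mom(mean: float, sd: float) -> DistributionSpec:
    """Fit a beta distribution by the method of moments.

    alpha = m (m(1-m)/s^2 - 1), beta = (1-m)(m(1-m)/s^2 - 1); feasible only
    when 0 < mean < 1 and 0 < sd^2 < mean(1-mean).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must lie strictly in (0, 1), got {mean}")
    var = sd * sd
    bound = mean * (1.0 - mean)
    if not 0.0 < var < bound:
        raise ValueError(
            f"infeasible beta moments: need 0 < sd^2 < mean(1-mean) = "
            f"{bound:.6g}, got sd^2 = {var:.6g}"
        )
    nu = bound / var - 1.0  # common factor alpha + beta
    return DistributionSpec("beta", mean * nu, (1.0 - mean) * nu, mean, sd)


def fit_gamma_mom(mean: float, sd: float) -> DistributionSpec:
    """Fit a gamma distribution by the method of moments.

    shape k = mean^2/sd^2, scale theta = sd^2/mean, so k*theta = mean exactly.
    """
    if not (mean > 0 and sd > 0):
        raise ValueError(f"gamma moments must be positive, got mean={mean}, sd={sd}")
    k = (mean / sd) ** 2
    theta = sd * sd / mean
    return DistributionSpec("gamma", k, theta, mean, sd)


class ClassificationError(ValueError):
    """A patient cannot be assigned a health state."""


def classify_state(alive: bool, krt: bool | None, egfr: float | None) -> HealthState:
    """Assign the 4-state classification for one patient at one time point.

    Dead dominates everything; among the living, KRT dependence dominates
    eGFR; otherwise eGFR >= 60 is no CKD and eGFR < 60 is CKD without KRT.
    """
    if not alive:
        return HealthState.DEAD
    if krt:
        return HealthState.KRT_DEPENDENT
    if egfr is None or (isinstance(egfr, float) and math.isnan(egfr)):
        raise ClassificationError(
            "alive patient without KRT must have an eGFR measurement"
        )
    if egfr >= EGFR_CKD_THRESHOLD:
        return HealthState.NO_CKD
    return HealthState.CKD_NO_KRT


def period_to_monthly(p_period: float, n_cycles: int) -> float:
    """Convert a period probability to a per-cycle one at constant hazard.

    Returns 1 - (1 - p)^(1/n); p = 0 and p = 1 are fixed points.
    """
    if not 0.0 <= p_period <= 1.0:
        raise ValueError(f"probability out of [0, 1]: {p_period}")
    if n_cycles < 1:
        raise ValueError(f"n_cycles must be >= 1, got {n_cycles}")
    return 1.0 - (1.0 - p_period) ** (1.0 / n_cycles)


@dataclass
class TransitionEstimate:
    """Estimated transition structure for one arm.

    ``matrix_period`` covers the whole day-90 -> day-365 window;
    ``matrix_monthly`` is its constant-hazard monthly adjustment; ``counts``
    are the raw transition counts.  Rows whose day-90 state had no occupants
    are listed in ``inestimable_rows`` and left as NaN rather than silently
    zero-filled — the caller must supply a fallback (e.g. published values).
    """

    counts: np.ndarray
    matrix_period: np.ndarray
    matrix_monthly: np.ndarray
    inestimable_rows: list[HealthState] = field(default_factory=list)

    def require_estimable(self) -> None:
        if self.inestimable_rows:
            names = ", ".join(s.name for s in self.inestimable_rows)
            raise ValueError(f"transition rows with no day-90 occupants: {names}")


def _monthly_row(row: np.ndarray, i: int, n_cycles: int) -> np.ndarray:
    # Off-diagonals via the competing constant-hazard form, the diagonal via
    # the survival form p^(1/n); renormalize so the row stays stochastic.
    out = np.empty_like(row)
    for j in range(row.size):
        if j == i:
            out[j] = row[j] ** (1.0 / n_cycles)
        else:
            out[j] = period_to_monthly(float(row[j]), n_cycles)
    total = out.sum()
    if total <= 0:
        raise ValueError(f"degenerate transition row {i}")
    return out / total


def classify_states_frame(df: pd.DataFrame, when: str) -> np.ndarray:
    """Vectorized :func:`classify_state` over a cohort frame.

    ``when`` is ``"90"`` or ``"365"``; returns an int array of HealthState
    values, raising :class:`ClassificationError` if any living non-KRT
    patient lacks an eGFR.
    """
    alive = df[f"alive_{when}"].astype(bool).to_numpy()
    krt = pd.to_numeric(df[f"krt_{when}"], errors="coerce").to_numpy(dtype=float)
    egfr = pd.to_numeric(df[f"egfr_{when}"], errors="coerce").to_numpy(dtype=float)
    states = np.full(len(df), int(HealthState.DEAD))
    on_krt = alive & (krt == 1.0)
    states[on_krt] = int(HealthState.KRT_DEPENDENT)
    non_krt = alive & ~on_krt
    missing = non_krt & np.isnan(egfr)
    if missing.any():
        idx = np.flatnonzero(missing)[:5].tolist()
        raise ClassificationError(
            f"alive non-KRT patients without eGFR at day {when}: rows {idx}"
        )
    states[non_krt & (egfr >= EGFR_CKD_THRESHOLD)] = int(HealthState.NO_CKD)
    states[non_krt & (egfr < EGFR_CKD_THRESHOLD)] = int(HealthState.CKD_NO_KRT)
    return states


def estimate_transition_matrix(
    records: pd.DataFrame | Iterable,
    n_cycles: int = N_CYCLES_90_TO_365,
) -> TransitionEstimate:
    """Estimate the 4x4 transition matrix from day-90/day-365 states.

    Each patient contributes one (state at 90 d, state at 365 d) pair; the
    period matrix is the row-normalized count matrix with the dead row forced
    to (0, 0, 0, 1), and the monthly matrix its constant-hazard adjustment
    over ``n_cycles`` cycles.
    """
    df = _as_dataframe(records)
    s90 = classify_states_frame(df, "90")
    s365 = classify_states_frame(df, "365")
    counts = (
        np.bincount(s90 * N_STATES + s365, minlength=N_STATES * N_STATES)
        .reshape(N_STATES, N_STATES)
        .astype(float)
    )

    period = np.full((N_STATES, N_STATES), np.nan)
    monthly = np.full((N_STATES, N_STATES), np.nan)
    inestimable: list[HealthState] = []
    for s in ALIVE_STATES:
        n_row = counts[s].sum()
        if n_row == 0:
            inestimable.append(s)
            continue
        period[s] = counts[s] / n_row
        monthly[s] = _monthly_row(period[s], int(s), n_cycles)
    period[HealthState.DEAD] = [0.0, 0.0, 0.0, 1.0]
    monthly[HealthState.DEAD] = [0.0, 0.0, 0.0, 1.0]
    return TransitionEstimate(counts, period, monthly, inestimable)


#: Published decomposition of post-90-day monthly cost across the alive
#: states (KRT dependent, CKD without KRT, no CKD).
DEFAULT_STATE_SHARES = (0.71, 0.17, 0.12)


def estimate_cost_params(
    records: pd.DataFrame | Iterable,
    state_shares: Sequence[float] = DEFAULT_STATE_SHARES,
) -> dict:
    """Summarize period costs per arm and decompose them across states.

    Per arm: mean/SD of the one-time 0-90 day cost, of the month-4
    (91-120 day) cost, and of the steady monthly (>120 day) cost.  State
    costs are the period total scaled by ``state_shares``
    (KRT, CKD, no-CKD order), matching how the study apportioned aggregate
    monthly cost; SDs scale by the same share.
    """
    shares = np.asarray(state_shares, dtype=float)
    if shares.shape != (3,):
        raise ValueError("state_shares must have 3 entries (KRT, CKD, no CKD)")
    if abs(shares.sum() - 1.0) > 1e-6:
        raise ValueError(f"state shares must sum to 1, got {shares.sum()}")
    df = _as_dataframe(records)
    out: dict = {"state_shares": tuple(shares)}
    period_cols = {
        "cost_0_90": "cost_0_90",
        "cost_91_120": "cost_91_120",
        "monthly_cost_121_365": "monthly_cost_121_365",
    }
    share_by_state = {
        HealthState.KRT_DEPENDENT: shares[0],
        HealthState.CKD_NO_KRT: shares[1],
        HealthState.NO_CKD: shares[2],
    }
    for arm in ARMS:
        sub = df[df["arm"] == arm]
        arm_out: dict = {}
        for key, col in period_cols.items():
            vals = sub[col].dropna().to_numpy(dtype=float)
            mean = float(vals.mean()) if vals.size else float("nan")
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            arm_out[key] = {"mean": mean, "sd": sd}
            if key != "cost_0_90":
                arm_out[key]["by_state"] = {
                    state.name: {
                        "mean": mean * share,
                        "sd": sd * share,
                    }
                    for state, share in share_by_state.items()
                }
        out[arm] = arm_out
    return out


def compute_state_shares(records: pd.DataFrame | Iterable) -> tuple[float, float, float]:
    """Share of total post-90-day monthly cost borne by each alive state.

    Costs are attributed to the patient's day-90 state; returns
    (KRT, CKD, no-CKD) shares summing to 1.
    """
    df = _as_dataframe(records)
    s90 = classify_states_frame(df, "90")
    cost = pd.to_numeric(df["monthly_cost_121_365"], errors="coerce").to_numpy(dtype=float)
    have = (s90 != int(HealthState.DEAD)) & ~np.isnan(cost)
    totals = {
        s: float(cost[have & (s90 == int(s))].sum()) for s in ALIVE_STATES
    }
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("total post-90-day monthly cost is zero; shares undefined")
    return (
        totals[HealthState.KRT_DEPENDENT] / grand,
        totals[HealthState.CKD_NO_KRT] / grand,
        totals[HealthState.NO_CKD] / grand,
    )


def _as_dataframe(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    from .synthetic import records_to_frame  # local import, avoids cycle

    return records_to_frame(list(records))


def _opt_float(value) -> float | None:
    if value is None:
        return None
    v = float(value)
    return None if math.isnan(v) else v


def _opt_bool(value) -> bool | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return bool(value)
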