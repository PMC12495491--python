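"""Calibrated per-cycle schedules for time-dependent transition probabilities.

The evidence summarizes each time-dependent monthly probability (the three
state-specific death probabilities and no-CKD -> CKD progression) as a mean
and a range over the 480-cycle horizon.  The schedule here is the simplest
shape consistent with that summary and with mortality rising over a
lifetime: log-linear (Gompertz-like) growth from the range minimum toward
the maximum,

    p_t = min_p * (max_p / min_p) ** (c * t / (n - 1)),   capped at max_p,

where the single calibration exponent ``c`` is solved so the vector mean
equals the published mean.  ``c`` is the one free scalar; it is reported so
a run manifest can reproduce the schedule exactly.  When the published
minimum is zero the log-linear start is replaced by a small positive floor
(max_p / 1000) before calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = ["MortalitySchedule", "generate_mortality_schedule"]

#: |vector mean - target| tolerance after calibration.
MEAN_TOL = 1e-3


@dataclass(frozen=True)
class MortalitySchedule:
    """A per-cycle probability vector with its calibration diagnostics."""

    probs: np.ndarray
    mean_target: float
    min_p: float
    max_p: float
    calibration_factor: float

    @property
    def mean(self) -> float:
        return float(self.probs.mean())

    @property
    def cv(self) -> float:
        """Coefficient of variation across cycles (spread of the schedule)."""
        m = self.mean
        return float(self.probs.std() / m) if m > 0 else 0.0

    def __post_init__(self) -> None:
        p = self.probs
        if (p < 0).any() or (p > self.max_p + 1e-12).any():
            raise ValueError("schedule entries outside [0, max_p]")
        if abs(self.mean - self.mean_target) > MEAN_TOL:
            raise ValueError(
                f"calibrated mean {self.mean:.6f} misses target {self.mean_target}"
            )


class CalibrationError(ValueError):
    """The requested mean cannot be reached within the given range."""


def _raw_schedule(lo: float, hi: float, c: float, n: int) -> np.ndarray:
    t = np.arange(n) / max(n - 1, 1)
    return np.minimum(lo * (hi / lo) ** (c * t), hi)


def generate_mortality_schedule(
    mean_target: float, min_p: float, max_p: float, n_cycles: int
) -> MortalitySchedule:
    """Build an increasing per-cycle schedule with the given mean and range.

    Raises :class:`CalibrationError` when ``mean_target`` lies outside
    ``[min_p, max_p]``.
    """
    if not 0.0 <= min_p <= max_p <= 1.0:
        raise CalibrationError(f"invalid range [{min_p}, {max_p}]")
    if not min_p <= mean_target <= max_p:
        raise CalibrationError(
            f"mean {mean_target} outside feasible range [{min_p}, {max_p}]"
        )
    if n_cycles < 1:
        raise CalibrationError("n_cycles must be >= 1")

    if min_p == max_p:
        probs = np.full(n_cycles, min_p)
        return MortalitySchedule(probs, mean_target, min_p, max_p, 0.0)

    lo = min_p if min_p > 0 else max_p / 1000.0
    if mean_target <= lo:
        # Degenerate: the target sits at (or below) the floor.
        probs = np.full(n_cycles, mean_target)
        return MortalitySchedule(probs, mean_target, min_p, max_p, 0.0)

    def mean_at(c: float) -> float:
        return float(_raw_schedule(lo, max_p, c, n_cycles).mean())

    # mean_at is increasing in c: c = 0 gives the constant lo, large c a
    # schedule pinned at max_p almost everywhere.
    c_hi = 1.0
    while mean_at(c_hi) < mean_target and c_hi < 1e4:
        c_hi *= 2.0
    if mean_at(c_hi) < mean_target:  # pragma: no cover - defensive
        raise CalibrationError("calibration failed to bracket the target mean")
    c = brentq(lambda x: mean_at(x) - mean_target, 0.0, c_hi, xtol=1e-12)
    probs = _raw_schedule(lo, max_p, c, n_cycles)
    return MortalitySchedule(probs, mean_target, min_p, max_p, float(c))
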