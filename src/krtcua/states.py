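"""Health states and trial arms for the KRT-initiation cost-utility model.

The model classifies each patient, 90 days after randomization and at every
subsequent monthly cycle, into one of four mutually exclusive states defined
by kidney function: no chronic kidney disease (eGFR >= 60 mL/min/1.73 m2),
CKD without dialysis dependence (eGFR < 60), alive and KRT dependent
(receiving dialysis), or dead.  Dead is absorbing.
"""

from __future__ import annotations

from enum import IntEnum


class HealthState(IntEnum):
    """The four Markov states, ordered as they index transition matrices."""

    NO_CKD = 0
    CKD_NO_KRT = 1
    KRT_DEPENDENT = 2
    DEAD = 3

    @property
    def is_alive(self) -> bool:
        return self is not HealthState.DEAD


#: States in matrix order.
STATES: tuple[HealthState, ...] = (
    HealthState.NO_CKD,
    HealthState.CKD_NO_KRT,
    HealthState.KRT_DEPENDENT,
    HealthState.DEAD,
)

#: The three alive (transient at entry) states.
ALIVE_STATES: tuple[HealthState, ...] = STATES[:3]

N_STATES = 4

# Trial arms: "accelerated" initiates KRT within 12 h of eligibility,
# "standard" defers until a conventional indication develops.
ARM_ACCELERATED = "accelerated"
ARM_STANDARD = "standard"
ARMS: tuple[str, str] = (ARM_ACCELERATED, ARM_STANDARD)


def check_arm(arm: str) -> str:
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    return arm
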