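import numpy as np
import pandas as pd
import pytest

from krtcua import ModelConfig, default_parameters
from krtcua.states import ARM_ACCELERATED, ARM_STANDARD


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture
def short_config():
    """A 24-cycle horizon: cheap runs that still exercise the machinery."""
    return ModelConfig(n_cycles=24)


def make_patient(
    pid="P0",
    arm=ARM_ACCELERATED,
    alive_90=True,
    alive_365=True,
    egfr_90=75.0,
    egfr_365=75.0,
    krt_90=0.0,
    krt_365=0.0,
    cost_0_90=1000.0,
    cost_91_120=100.0,
    monthly_cost_121_365=50.0,
    utility_90=0.8,
    utility_365=0.8,
    age=61.0,
):
    """One cohort row, in the CSV column layout, with sensible defaults."""
    if not alive_90:
        alive_365 = False
        egfr_90 = egfr_365 = krt_90 = krt_365 = np.nan
        cost_91_120 = monthly_cost_121_365 = np.nan
        utility_90 = utility_365 = np.nan
    elif not alive_365:
        egfr_365 = krt_365 = utility_365 = np.nan
    return dict(
        patient_id=pid,
        arm=arm,
        age=age,
        alive_90=alive_90,
        alive_365=alive_365,
        egfr_90=egfr_90,
        egfr_365=egfr_365,
        krt_90=krt_90,
        krt_365=krt_365,
        cost_0_90=cost_0_90,
        cost_91_120=cost_91_120,
        monthly_cost_121_365=monthly_cost_121_365,
        utility_90=utility_90,
        utility_365=utility_365,
    )


def cohort_frame(rows):
    return pd.DataFrame(rows)


@pytest.fixture
def two_arm_cohort():
    """A tiny but complete two-arm cohort covering every state."""
    rows = []
    for arm, tag in ((ARM_ACCELERATED, "A"), (ARM_STANDARD, "S")):
        rows += [
            make_patient(f"{tag}0", arm, egfr_90=80, egfr_365=80),
            make_patient(f"{tag}1", arm, egfr_90=45, egfr_365=45),
            make_patient(f"{tag}2", arm, krt_90=1.0, krt_365=1.0, egfr_90=30, egfr_365=30),
            make_patient(f"{tag}3", arm, alive_365=False, egfr_90=70),
            make_patient(f"{tag}4", arm, alive_90=False),
            make_patient(f"{tag}5", arm, egfr_90=50, egfr_365=65),
        ]
    return cohort_frame(rows)
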