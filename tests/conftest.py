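import numpy as np
import pytest

from csfsink import KineticParams, TherapySchedule
from csfsink.kinetics import GridSpec
from csfsink.params import IMMEDIATE


@pytest.fixture
def kp():
    return KineticParams()


@pytest.fixture
def fine_grid():
    return GridSpec(t_end=220.0, dt=0.01)


@pytest.fixture(scope="session")
def default_comparison():
    """One shared run of the default three-arm comparison."""
    from csfsink.scenarios import run_cohort_comparison

    return run_cohort_comparison()


def random_scenario(rng: np.random.Generator, t_end: float = 30.0):
    """Random valid (schedule, params) pair for oracle-equivalence tests."""
    params = KineticParams(
        a0=float(rng.uniform(0.0, 500.0)),
        p_prod=float(rng.uniform(0.0, 400.0)),
        c_nat=float(rng.uniform(0.02, 1.0)),
        c_it=float(rng.uniform(0.0, 2.0)),
        e_dose=float(rng.uniform(0.0, 0.9)),
        tau_dose=float(rng.uniform(0.25, 2.0)),
    )
    arm = rng.choice(["untreated", "intrathecal", "iv"])
    t_start = float(rng.uniform(0.0, t_end / 2))
    t_stop = None
    washout = IMMEDIATE
    if arm != "untreated" and rng.random() < 0.5:
        t_stop = float(rng.uniform(t_start + 1.0, t_end))
        if rng.random() < 0.5:
            washout = float(rng.uniform(0.05, 2.0))
    schedule = TherapySchedule(
        arm=str(arm), t_start=t_start, t_stop=t_stop, washout_rate=washout
    )
    return schedule, params
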