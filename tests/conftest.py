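import numpy as np
import pytest

from swimnet.metrics import SwimmerSession, TrialTiming
from swimnet.simulate import CohortSimConfig, simulate_cohort


def make_session(swimmer_id="S01", sex="F", age=10.0, height=140.0,
                 sitting_height=74.0, arm_span=142.0, body_mass=34.0,
                 trials=None):
    if trials is None:
        trials = {
            "BREAST": TrialTiming(t25=32.0, t10=12.5, t3cycles=4.0),
            "FLY": TrialTiming(t25=30.0, t10=12.0, t3cycles=4.5),
        }
    return SwimmerSession(
        swimmer_id=swimmer_id, sex=sex, age=age, height=height,
        sitting_height=sitting_height, arm_span=arm_span,
        body_mass=body_mass, trials=trials,
    )


@pytest.fixture
def session_factory():
    return make_session


@pytest.fixture(scope="session")
def default_cohort():
    """One simulated 20-swimmer cohort at the default targets, fixed seed."""
    return simulate_cohort(CohortSimConfig(seed=2022))


@pytest.fixture(scope="session")
def large_cohort():
    """A 200-swimmer cohort for calibration checks (same sex ratio)."""
    return simulate_cohort(CohortSimConfig(n_girls=110, n_boys=90, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
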