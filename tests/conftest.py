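import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import motionprims as mp

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def desk_cohort():
    """Six virtual subjects performing the reduced protocol at 60 Hz."""
    return mp.simulate_cohort(
        mp.desk_protocol(), mp.default_subjects(6), seed=11, sample_rate=60
    )


@pytest.fixture(scope="session")
def desk_table(desk_cohort):
    return mp.featurize_cohort(desk_cohort)


@pytest.fixture(scope="session")
def tiny_recording():
    """One subject, one move (4 primitives), 60 Hz."""
    protocol = mp.TaskProtocol(n_trials=1, n_targets=1, objects=("can",))
    return mp.simulate_recording(
        protocol, mp.SubjectParams("s01"), seed=7, sample_rate=60
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
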