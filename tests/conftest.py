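import numpy as np
import pytest

from probecal.simulate import (
    AcquisitionPlan,
    NoiseModel,
    default_system_truth,
    simulate_observations,
)


@pytest.fixture(scope="session")
def truth():
    return default_system_truth()


@pytest.fixture(scope="session")
def noiseless_obs(truth):
    """Full-FOV cross-wire acquisition, exact measurements (40 targets)."""
    plan = AcquisitionPlan(phantom_kind="cross_wire", coverage="full_fov")
    return simulate_observations(truth, plan, NoiseModel.noiseless())


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
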