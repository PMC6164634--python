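import numpy as np
import pytest

from araquant import ArmModel, ImpairmentProfile, TaskSpec, generate_task


@pytest.fixture(scope="session")
def model():
    return ArmModel()


@pytest.fixture(scope="session")
def unit_model():
    """Unit segment lengths, shoulder at the trunk origin: easy hand math."""
    return ArmModel(
        handedness="right",
        upper_arm_m=1.0,
        forearm_m=1.0,
        hand_m=1.0,
        shoulder_offset=np.zeros(3),
    )


@pytest.fixture(scope="session")
def healthy_recording():
    return generate_task(TaskSpec.grasp(), ImpairmentProfile.preset("H"), seed=42)


@pytest.fixture(scope="session")
def impaired_recording():
    return generate_task(TaskSpec.grasp(), ImpairmentProfile.preset("AF2"), seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
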