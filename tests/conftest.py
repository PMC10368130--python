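import warnings

import numpy as np
import pytest

from rehabmotion.kinematics import ArmModel
from rehabmotion.simulate import ImpairmentSpec, generate_trajectory

warnings.filterwarnings("ignore", message="Gimbal lock")


@pytest.fixture(scope="session")
def arm_models():
    return ArmModel(side="right"), ArmModel(side="left")


@pytest.fixture(scope="session")
def sweep_sim():
    """A clean full-ROM vertical sweep, 10 fps."""
    return generate_trajectory("RW-V90", ImpairmentSpec(), fps=10, seed=1)


@pytest.fixture(scope="session")
def proximal_sim():
    """A clean nose-touch reach, 10 fps."""
    return generate_trajectory("Nose", ImpairmentSpec(), fps=10, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
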