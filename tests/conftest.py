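import numpy as np
import pytest
from hypothesis import settings

from imukin import (FusionSettings, NoiseModel, estimate_gyro_bias,
                    load_default_model, static_trajectory, synthesize)
from imukin.calibration import calibrate
from imukin.rotations import Quaternion

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def random_quaternion(rng: np.random.Generator) -> Quaternion:
    """Uniform random rotation (Shoemake's method via normalized 4-vector)."""
    v = rng.normal(size=4)
    return Quaternion(*v)


@pytest.fixture(scope="session")
def lower_limb():
    return load_default_model("lower_limb")


@pytest.fixture(scope="session")
def full_body():
    return load_default_model("full_body")


@pytest.fixture(scope="session")
def static_streams(lower_limb):
    """Noiseless 12-s standing recording for every lower-limb segment."""
    return synthesize(lower_limb, static_trajectory(12.0), 100.0,
                      NoiseModel.noiseless())


@pytest.fixture(scope="session")
def standing_calibration(lower_limb, static_streams):
    biases = {s: estimate_gyro_bias(st, 10.0)
              for s, st in static_streams.items()}
    return calibrate(lower_limb, static_streams, FusionSettings(), biases)


GAIT_AMPLITUDES = {
    "hip_flexion_r": 30.0, "hip_flexion_l": 30.0,
    "knee_flexion_r": 35.0, "knee_flexion_l": 35.0,
    "ankle_flexion_r": 15.0, "ankle_flexion_l": 15.0,
}
GAIT_MEANS = {"knee_flexion_r": 35.0, "knee_flexion_l": 35.0}
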