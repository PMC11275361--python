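import numpy as np
import pytest

from probetrack import (
    CameraModel,
    build_dodecahedron,
    calibrate,
)
from probetrack.synthetic import SimConfig, simulate, simulate_calibration_snapshot


@pytest.fixture(scope="session")
def model():
    return build_dodecahedron()


@pytest.fixture(scope="session")
def camera():
    return CameraModel(fx=900.0, fy=900.0, cx=640.0, cy=360.0,
                       dist=np.zeros(5), width=1280, height=720)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def noiseless_cfg():
    """Short noiseless sweep shared by round-trip tests."""
    return SimConfig(duration=1.0, seed=42)


@pytest.fixture(scope="session")
def noiseless_sim(noiseless_cfg):
    return simulate(noiseless_cfg)


@pytest.fixture(scope="session")
def noiseless_calibration(noiseless_cfg):
    return calibrate(simulate_calibration_snapshot(noiseless_cfg))
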