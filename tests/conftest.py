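import numpy as np
import pytest

from tiltsheet.optics import CameraModel, DetectionModel, field_center_um


@pytest.fixture
def det64():
    return DetectionModel(fov_px=(64, 64))


@pytest.fixture
def camera():
    return CameraModel()


@pytest.fixture
def quiet_camera():
    """Low-noise camera for tests that probe signal structure."""
    return CameraModel(em_gain=50.0, offset=100.0, read_noise_counts=2.0, qe=0.9)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def center64(det64):
    return field_center_um(det64)
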