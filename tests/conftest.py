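import numpy as np
import pytest

from scmosfit import CalibrationMap, synth_calibration


@pytest.fixture(scope="session")
def striped_camera() -> CalibrationMap:
    """Reference synthetic sensor: 4% gain/RQE std, anti-correlated, striped."""
    calib = synth_calibration((96, 96), seed=42)
    calib.pixel_size_nm = 100.0
    return calib


@pytest.fixture(scope="session")
def uniform_camera() -> CalibrationMap:
    """Idealized camera: uniform gain 2, offset 100, read noise 9 ADU^2."""
    return CalibrationMap.uniform(
        (64, 64), offset=100.0, variance=9.0, gain=2.0, rqe=1.0, pixel_size_nm=100.0
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
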