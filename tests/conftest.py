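import numpy as np
import pytest

from arterynotch import (
    ArteryGeometry,
    MaterialParameters,
    NotchParameters,
    build_fiber_set,
    calibrate_opening_angle,
)


@pytest.fixture(scope="session")
def params():
    """Published coronary-artery material constants."""
    return MaterialParameters()


@pytest.fixture(scope="session")
def fibers(params):
    return build_fiber_set(params)


@pytest.fixture(scope="session")
def geom():
    return ArteryGeometry()


@pytest.fixture(scope="session")
def notch_params():
    return NotchParameters()


@pytest.fixture(scope="session")
def calibrated_phi(geom, params, fibers):
    """Opening angle calibrated once per session at 100 mmHg."""
    return calibrate_opening_angle(geom, params, fibers, lambda_axial=1.39)


@pytest.fixture()
def rng():
    return np.random.default_rng(20220629)
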