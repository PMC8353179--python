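import numpy as np
import pytest

from qcest import (
    CrystalliteOrientation,
    ExchangeNetwork,
    ExperimentParams,
    QuadrupolarTensor,
    Site,
    two_site_flip,
)

CQ_METHYL_AVG = 55.3e3  # Hz, methyl-averaged DMS coupling
CQ_STATIC = 165.9e3  # Hz, static methyl coupling (3 x averaged)
JUMP_ANGLE = np.deg2rad(106.0)
CONE_ANGLE = np.deg2rad(109.47)


@pytest.fixture(scope="session")
def single_site_network():
    """One rigid axially symmetric site, no exchange (no-motion reference)."""
    return ExchangeNetwork([Site(QuadrupolarTensor(CQ_METHYL_AVG), 1.0)], np.zeros((1, 1)))


@pytest.fixture(scope="session")
def dms_network():
    """DMS-like two-site rotameric flip at its high-temperature flip rate."""
    return two_site_flip(CQ_METHYL_AVG, 0.0, JUMP_ANGLE, 9000.0)


@pytest.fixture(scope="session")
def dms_params():
    return ExperimentParams(rf_hz=1300.0, offset_hz=0.0, mas_hz=25e3, t1=41e-3)


@pytest.fixture
def orientation():
    return CrystalliteOrientation(0.8, 1.2)
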