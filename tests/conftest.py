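import numpy as np
import pytest

from npfcs import DetectionVolume, PhysicalConditions


@pytest.fixture(scope="session")
def volume() -> DetectionVolume:
    """Typical calibrated detection volume: omega0 = 350 nm, S = 11."""
    return DetectionVolume(350e-9, 11.0)


@pytest.fixture(scope="session")
def water() -> PhysicalConditions:
    """Water at 21 degC (294.15 K, 0.978 mPa s)."""
    return PhysicalConditions()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
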