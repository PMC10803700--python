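import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import petisl

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def diq():
    return petisl.DIQ_LIKE


@pytest.fixture(scope="session")
def dmi():
    return petisl.DMI_LIKE


@pytest.fixture
def uniform_vol():
    """A uniform 5 kBq/mL volume on the coarser clinical grid."""
    return petisl.Volume3D.from_spacing(
        np.full((40, 40, 30), 5.0), (2.34, 2.34, 3.26)
    )


@pytest.fixture
def gradient_vol():
    """A volume with a linear AC gradient along x (in kBq/mL)."""
    nx, ny, nz = 40, 40, 30
    x = np.arange(nx, dtype=float)[:, None, None]
    data = 2.0 + 0.05 * np.broadcast_to(x, (nx, ny, nz))
    return petisl.Volume3D.from_spacing(data.copy(), (2.34, 2.34, 3.26))


@pytest.fixture(scope="session")
def scan_meta():
    return petisl.default_scan_meta()


@pytest.fixture(scope="session")
def small_phantom_spec():
    return petisl.default_phantom_spec(shape=(48, 48, 36))
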