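import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from qusatten.rf_simulator import ProbeGeometry, build_phantom

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def probe() -> ProbeGeometry:
    return ProbeGeometry()


@pytest.fixture(scope="session")
def small_probe() -> ProbeGeometry:
    """32-element probe for cheap point-scatterer scenes."""
    return ProbeGeometry(n_elements=32)


@pytest.fixture(scope="session")
def small_phantom_cfg() -> dict:
    """Unattenuated scene matching the small probe's aperture."""
    return {
        "background": {"alpha0": 0.0, "echogenicity": 1.0},
        "extent": [32 * 298e-4, 4.0],
    }


@pytest.fixture(scope="session")
def weak_phantom():
    return build_phantom("cirs_weak")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
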