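import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pascan.acquisition import InstrumentConfig
from pascan.synthetic_skin import make_wavenumber_grid

settings.register_profile(
    "repro",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def grid():
    """The instrument's spectral sweep: 950-1240 cm^-1 at 1.38 cm^-1/point."""
    return make_wavenumber_grid(950.0, 1240.0, 1.38)


@pytest.fixture()
def quiet_instrument():
    """Instrument with noise disabled, for deterministic forward-model checks."""
    return InstrumentConfig(noise_sigma=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
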