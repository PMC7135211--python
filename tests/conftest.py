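import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from rimmune.phantoms import LatentImmuneState, PhantomConfig, generate_phantom
from rimmune.radiomics import default_catalog


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Deterministic phantom: no noise, spherical, known rim contrast 40 HU."""
    cfg = PhantomConfig(seed=1, noise_sd_hu=1e-9, axis_jitter=1e-6)
    return generate_phantom(cfg, LatentImmuneState("S0")), cfg


@pytest.fixture(scope="session")
def noisy_phantom():
    """A single phantom at the default study conditions."""
    cfg = PhantomConfig(seed=2)
    return generate_phantom(cfg, LatentImmuneState("S0", th2_level=0.5)), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
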