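import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from napkit.simulate import SimConfig, simulate_libraries, simulate_world


@pytest.fixture(scope="session")
def world():
    """A small deterministic world with every napRNA class implanted."""
    return simulate_world(SimConfig(rng_seed=7))


@pytest.fixture(scope="session")
def noiseless_run():
    """Noiseless two-sample libraries with fully retained adapters."""
    cfg = SimConfig(
        rng_seed=11, n_samples=2, adapter_retention_prob=1.0, background_read_rate=0.0
    )
    w = simulate_world(cfg)
    return w, simulate_libraries(w)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
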