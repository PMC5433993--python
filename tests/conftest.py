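import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ddonmix as dx

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def basic_sim():
    """One default-design dataset with truth (4 species, 20 plots, 3 visits)."""
    return dx.simulate_basic(dx.SimConfig(seed=42))


@pytest.fixture(scope="session")
def basic_fit(basic_sim):
    """A short but converged fit of the basic model, reused across tests."""
    data, truth = basic_sim
    samples = dx.fit(
        data,
        dx.ModelSpec(),
        dx.Priors(),
        dx.MCMCConfig(n_chains=3, n_iter=3000, n_burn=800, seed=7),
    )
    return data, truth, samples


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
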