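import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from etrfit.fit_engine import FitConfig
from etrfit.synthetic_data import DEFAULT_FVCB_TRUTH, ScenarioConfig, gen_aci

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def light_config():
    """Reduced annealing budget for multi-fit tests; polish still makes the
    result a local SSE minimum."""
    return FitConfig(seed=5, sweeps=100, proposals_per_sweep=30)


@pytest.fixture(scope="session")
def noiseless_aci():
    """One noiseless A-Ci replicate of the default ground truth."""
    return gen_aci(ScenarioConfig(truth=DEFAULT_FVCB_TRUTH, n_reps=1, noise_sd=0.0, seed=1))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
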