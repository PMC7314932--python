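import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import elicitlgm as el
from elicitlgm.lgm import _reduced_config

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def truth():
    """Default data-generating truth used across the suite."""
    return el.TruthConfig(seed=42, clip=False)


@pytest.fixture(scope="session")
def sim_data(truth):
    """One model-consistent n=100 synthetic dataset."""
    return el.simulate_scores(truth)


@pytest.fixture(scope="session")
def reduced_mcmc():
    """Sampler settings small enough for repeated fits in the suite."""
    return _reduced_config()


@pytest.fixture(scope="session")
def ref_fit(sim_data, reduced_mcmc):
    """Benchmark-2 reference posterior on the shared synthetic dataset."""
    model = el.LatentGrowthModel(sim_data, el.default_benchmark_spec("benchmark2"))
    return model.fit(seed=7, config=reduced_mcmc)
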