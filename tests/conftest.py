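import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import quailfcm as q

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    return q.GeneratorConfig(seed=42)


@pytest.fixture(scope="session")
def cohort(default_config):
    return q.make_cohort(default_config)


@pytest.fixture(scope="session")
def samples(default_config, cohort):
    """Full synthetic study at the default truths (24 birds)."""
    return q.simulate_fcm(cohort, default_config)


@pytest.fixture(scope="session")
def noise_free_samples():
    """Degenerate generator: no individual variation, no residual noise,
    every window collected."""
    cfg = q.GeneratorConfig(
        seed=5, true_sigma_k=np.zeros(8), residual_sd=0.0, defecation_prob=1.0)
    return q.simulate_fcm(q.make_cohort(cfg), cfg), cfg


@pytest.fixture(scope="session")
def small_fit(samples):
    """A short but converged fit reused by diagnostics/trajectory tests."""
    data = q.build_design(samples)
    cfg = q.McmcConfig(n_chains=3, n_iter=1500, n_burn=500, seed=9)
    return q.run_mcmc(data, cfg)
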