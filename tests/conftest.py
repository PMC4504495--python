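import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def mixed_ensemble():
    """A fast-mixing two-state ensemble with explicit water positions."""
    from poregate import synthetic

    model = synthetic.default_wetting_model(wetting_rate=3.0e8,
                                            wet_occupancy=0.3)
    return synthetic.simulate_wetting_ensemble(
        model, n_traj=60, duration=35.0, dt=0.1, seed=2024,
        include_positions=True)
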