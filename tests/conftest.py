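import numpy as np
import pytest

from needledyn.synth import ExperimentConfig, simulate_experiment


@pytest.fixture(scope="session")
def default_config():
    return ExperimentConfig(rng_seed=1)


@pytest.fixture(scope="session")
def default_simulation(default_config):
    """One shared default-scenario simulation (seed 1)."""
    return simulate_experiment(default_config)


@pytest.fixture(scope="session")
def small_simulation():
    """A reduced experiment (4 seedlings/treatment, 4 days) for fast tests."""
    cfg = ExperimentConfig(
        n_seedlings_per_treatment=4, n_days=4, wilt_onset_session="D2E",
        physio_effect_day="D3M", rng_seed=7
    )
    return simulate_experiment(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape=(16, 16), p=0.4):
    """Random boolean mask, guaranteed nonempty."""
    m = rng.random(shape) < p
    if not m.any():
        m[shape[0] // 2, shape[1] // 2] = True
    return m


@pytest.fixture(scope="session")
def default_full_pipeline(default_simulation):
    """Full analysis of the shared default simulation."""
    from needledyn.detect import analyze_simulation

    return analyze_simulation(default_simulation)
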