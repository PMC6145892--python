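import numpy as np
import pytest

from clipribo.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """One small but complete simulated experiment shared across tests."""
    cfg = SimulationConfig(
        n_transcripts=60,
        clip_depth=120_000,
        mrna_depth=100_000,
        rpf_depth=100_000,
        target_fraction=0.4,
        seed=42,
    )
    return simulate_experiment(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
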