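import numpy as np
import pytest

from nmaloo import ArmRecord, MCMCConfig, NMANetwork


@pytest.fixture
def toy_network() -> NMANetwork:
    """Four trials on four treatments with one closed loop:
    S1:(T1,T2) S2:(T1,T3) S3:(T2,T3) S4:(T3,T4)."""
    arms = (
        ArmRecord("S1", "T1", 10, 50), ArmRecord("S1", "T2", 15, 50),
        ArmRecord("S2", "T1", 12, 60), ArmRecord("S2", "T3", 20, 60),
        ArmRecord("S3", "T2", 18, 55), ArmRecord("S3", "T3", 22, 55),
        ArmRecord("S4", "T3", 9, 40), ArmRecord("S4", "T4", 14, 40),
    )
    return NMANetwork(("T1", "T2", "T3", "T4"), arms, "beneficial", "toy")


@pytest.fixture
def tiny_mcmc() -> MCMCConfig:
    """Ultra-small profile for structural (non-inferential) fit tests."""
    return MCMCConfig(n_chains=2, n_adapt=150, n_burnin=100, n_iter=300,
                      thin=1, seed=123)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
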