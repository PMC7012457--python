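import numpy as np
import pytest

from collareffects.bayescore import MCMCSettings


@pytest.fixture
def fast_settings():
    """Small-but-honest MCMC settings for quick unit-test fits."""
    return MCMCSettings(n_chains=3, n_iter=6000, burn_in=0.3, thin=5, seed=0)


@pytest.fixture
def tiny_settings():
    """Minimal settings for tests that only exercise plumbing."""
    return MCMCSettings(n_chains=2, n_iter=1500, burn_in=0.2, thin=3, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
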