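import numpy as np
import pytest
from hypothesis import settings

import evoisol as ev

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")


@pytest.fixture
def rng():
    return np.random.default_rng(20240528)


@pytest.fixture
def small_counts():
    """A small simulated count matrix with known injected structure."""
    cfg = ev.SimConfig(seed=42, n_genes=400)
    return ev.simulate_counts(cfg, 5)
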