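import numpy as np
import pytest


@pytest.fixture(scope="session")
def binary_design():
    """253/253 two-group design: intercept + 0/1 phenotype."""
    x = np.concatenate([np.ones(253), np.zeros(253)])
    return np.column_stack([np.ones(506), x])


@pytest.fixture()
def rng():
    return np.random.default_rng(20240301)
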