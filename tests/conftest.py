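import numpy as np
import pytest

import trajlm


@pytest.fixture(scope="session")
def two_state_chain():
    """A 0.9/0.1 two-state chain realization with its spec."""
    P = np.array([[0.9, 0.1], [0.1, 0.9]])
    spec = trajlm.MarkovChainSpec(P, length=50_000, seed=7)
    return spec, trajlm.sample_chain(spec)


@pytest.fixture(scope="session")
def three_state_chain():
    """An asymmetric irreducible 3-state chain with all entries >= 0.05."""
    P = np.array([
        [0.80, 0.15, 0.05],
        [0.10, 0.80, 0.10],
        [0.05, 0.25, 0.70],
    ])
    spec = trajlm.MarkovChainSpec(P, length=100_000, seed=13)
    return spec, trajlm.sample_chain(spec)


@pytest.fixture(scope="session")
def tiny_rng():
    return np.random.default_rng(42)
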