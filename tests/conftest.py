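import numpy as np
import pytest

from transportome.synthetic import (
    dedicated_transporters,
    neurospora_like,
    simulate_transportome,
)


@pytest.fixture(scope="session")
def noiseless_truth():
    """Paper-scale preset simulated without noise."""
    return simulate_transportome(neurospora_like(noise_cv=0.0, seed=11))


@pytest.fixture(scope="session")
def dedicated_truth():
    """One dedicated transporter per sugar, no noise."""
    return simulate_transportome(dedicated_transporters(noise_cv=0.0, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240115)
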