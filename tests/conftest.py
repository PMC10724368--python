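import numpy as np
import pytest

from rhinet.model import BodyOwnershipModel
from rhinet.network import NetworkConfig


@pytest.fixture(scope="session")
def default_config():
    return NetworkConfig()


@pytest.fixture(scope="session")
def trained():
    """Five independently trained replicates of the default model.

    Shared across the suite: unsupervised congruent babbling, 500 trials
    per replicate.
    """
    return BodyOwnershipModel().fit(n_trials=500, n_replicates=5, seed=0)


@pytest.fixture(scope="session")
def drift_curve(trained):
    return trained.drift_sweep()


def per_replicate(trained, fn):
    """Apply ``fn(network)`` to every replicate and return the list."""
    return [fn(net) for net in trained.networks]
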