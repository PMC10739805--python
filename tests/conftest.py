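import numpy as np
import pytest

from emtdyn import EnsembleConfig, GeneCircuit, run_ensemble


@pytest.fixture(scope="session")
def circuit():
    return GeneCircuit.default()


@pytest.fixture(scope="session")
def small_ensemble(circuit):
    """A reduced control ensemble shared across read-only tests."""
    cfg = EnsembleConfig(n_models=300, seed=11)
    return run_ensemble(circuit, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
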