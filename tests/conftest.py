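import numpy as np
import pytest

from wnphase.signal_models import ObserverConfig, generate_observer


@pytest.fixture(scope="session")
def small_observer():
    """A modest synthetic-observer dataset shared across tests."""
    return generate_observer(ObserverConfig(n_sequences=40, seed=1234))


@pytest.fixture(scope="session")
def noiseless_observer():
    """Deterministic observer: no sensor noise, no phase modulation."""
    cfg = ObserverConfig(n_sequences=12, noise_sd=0.0, det_mod=0.0, seed=77)
    return generate_observer(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
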