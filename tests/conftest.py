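import numpy as np
import pytest

from somnostat.spectral import BIN_FREQS, N_BINS
from somnostat.synthetic import SimConfig, default_genotypes, simulate_hypnogram
from somnostat.vigilance import Hypnogram


@pytest.fixture(scope="session")
def genotypes():
    return default_genotypes()


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free simulation config for exact closed-loop checks."""
    return SimConfig(seed=1, noise_sigma=0.0)


@pytest.fixture(scope="session")
def hyp_a(genotypes, sim_config):
    """One 72-h genotype_a hypnogram, shared across tests."""
    return simulate_hypnogram(genotypes["genotype_a"], sim_config, subject_id=0)


def make_hypnogram(states, artifact=None, start_s=0):
    states = np.asarray(list(states) if isinstance(states, str) else states)
    n = len(states)
    if artifact is None:
        artifact = np.zeros(n, dtype=bool)
    zt = start_s + 4 * np.arange(n)
    return Hypnogram(zt_seconds=zt, states=states, artifact=np.asarray(artifact))


@pytest.fixture
def uniform_power():
    def _make(n_epochs, value=1.0):
        return np.full((n_epochs, N_BINS), value)

    return _make
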