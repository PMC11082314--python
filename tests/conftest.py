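import numpy as np
import pytest

from emgdecode.preprocess import build_epochsets
from emgdecode.synthio import SynthConfig, synthesize_dataset


@pytest.fixture(scope="session")
def small_config():
    """Small guided-gesture benchmark: 2 subjects x 2 sessions."""
    return SynthConfig(n_subjects=2, n_sessions=2, rng_seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(phasic, tonic) epoch sets from the small benchmark."""
    return build_epochsets(synthesize_dataset(small_config))


@pytest.fixture(scope="session")
def small_phasic(small_dataset):
    return small_dataset[0]


@pytest.fixture(scope="session")
def small_tonic(small_dataset):
    return small_dataset[1]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_spd(rng, d=6, spread=2.0):
    """Random SPD matrix with log-uniform eigenvalues."""
    q = np.linalg.qr(rng.standard_normal((d, d)))[0]
    ev = np.exp(rng.uniform(-spread, spread, d))
    return (q * ev) @ q.T
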