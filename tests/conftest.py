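import numpy as np
import pytest

from audscene.signal import Waveform
from audscene.synthetic_data import make_category_bank


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noise_2p5s():
    """2.5 s of seeded Gaussian noise at the front end's native 48 kHz."""
    gen = np.random.default_rng(7)
    return Waveform(0.01 * gen.standard_normal(int(2.5 * 48000)), 48000)


@pytest.fixture(scope="session")
def noise_1s_44k():
    """1 s of seeded Gaussian noise at the experiment-native 44.1 kHz."""
    gen = np.random.default_rng(8)
    return Waveform(0.01 * gen.standard_normal(44100), 44100)


@pytest.fixture(scope="session")
def small_bank():
    """Six-category bank with three exemplars each (shared across tests)."""
    return make_category_bank(6, 3, seed=99)
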