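import numpy as np
import pytest

from synxqsl import DEFAULT_SCHEME, make_rng
from synxqsl.synthesis import ParameterRanges, SynthesisConfig, generate_dataset


@pytest.fixture(scope="session")
def scheme():
    return DEFAULT_SCHEME


@pytest.fixture()
def rng():
    return make_rng(1234)


@pytest.fixture(scope="session")
def ranges():
    return ParameterRanges()


@pytest.fixture(scope="session")
def small_noisy_dataset():
    """2000 quadratic-pattern samples at NR = 0.1 (shared, read-only)."""
    return generate_dataset(SynthesisConfig(n=2000, mode=6, nr=0.1, seed=11))


@pytest.fixture(scope="session")
def small_clean_dataset():
    """2000 quadratic-pattern samples without noise (shared, read-only)."""
    return generate_dataset(SynthesisConfig(n=2000, mode=6, nr=0.0, seed=12))


@pytest.fixture()
def uniform_volume(scheme):
    """A noise-free 8x8x3 volume with uniform (S0=1000, D=1e-3, K=0.8)."""
    from synxqsl.dki import dki_signal

    sig = dki_signal(scheme.b, S0=1000.0, D=1.0e-3, K=0.8)
    vol = np.broadcast_to(sig, (8, 8, 3, scheme.b.size)).copy()
    return vol
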