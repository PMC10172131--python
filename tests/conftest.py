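import numpy as np
import pytest

from neuroclr.data import make_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_session(rng):
    """100 time points, 5 signal dims, 2-D continuous + binary discrete."""
    signal = rng.standard_normal((100, 5))
    cont = rng.standard_normal((100, 2))
    disc = rng.integers(0, 2, size=100)
    return make_session(signal, continuous_context=cont,
                        discrete_context=disc)


@pytest.fixture
def linear_context_session(rng):
    """1-D context 0, 1, ..., T-1 (brute-force oracle-friendly)."""
    T = 200
    signal = rng.standard_normal((T, 3))
    return make_session(signal, continuous_context=np.arange(T, dtype=float))
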