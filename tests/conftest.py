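import numpy as np
import pytest

from ramanci import Spectrum


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def axis():
    """A 200-1500 cm^-1 grid at 1 cm^-1, containing every default anchor."""
    return np.arange(200.0, 1501.0)


@pytest.fixture
def random_spectrum(axis, rng):
    def make(seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        base = 2.0 + 0.002 * (axis - 200.0)
        peaks = sum(
            a * np.exp(-0.5 * ((axis - c) / w) ** 2)
            for a, c, w in ((5, 380, 8), (8, 1096, 9), (2, 1330, 12))
        )
        noise = r.normal(0, 0.05, axis.size)
        return Spectrum(axis, base + peaks + noise, sample_id="rand")

    return make
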