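import numpy as np
import pytest

from burstlab.filters import DEFAULT_BANDS, design_band_filter

FS = 250.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def band_filters():
    """All default band filters designed once for the whole session."""
    return {b.label: design_band_filter(b, FS) for b in DEFAULT_BANDS}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_sine_cycles(freq_hz=6.0, n_cycles=20, fs_hz=FS, amplitude=10.0):
    """A plain sinusoid starting at an ascending zero-crossing."""
    t = np.arange(int(n_cycles * fs_hz / freq_hz)) / fs_hz
    return amplitude * np.sin(2 * np.pi * freq_hz * t)
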