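import numpy as np
import pytest


@pytest.fixture(scope="session")
def tone():
    """1 s of a unit 10 Hz cosine at 1 kHz."""
    t = np.arange(1000) / 1000.0
    return np.cos(2 * np.pi * 10 * t), 1000.0


@pytest.fixture(scope="session")
def two_tone():
    """4 Hz + 18 Hz mixture, 1 s at 1 kHz."""
    t = np.arange(1000) / 1000.0
    return (np.sin(2 * np.pi * 4 * t) + 0.6 * np.sin(2 * np.pi * 18 * t),
            1000.0)


@pytest.fixture(scope="session")
def small_leadfield():
    from oscillosource.synthdata import make_spherical_leadfield
    return make_spherical_leadfield(16, 120, seed=3)


@pytest.fixture(scope="session")
def dense_leadfield():
    """Full 61-channel montage over a 300-vertex cortical sphere."""
    from oscillosource.synthdata import make_spherical_leadfield
    return make_spherical_leadfield(61, 300, seed=3)


def dominant_frequency(x, fs):
    """Periodogram-peak oracle used across tests."""
    from scipy.signal import periodogram
    f, p = periodogram(np.asarray(x, float), fs=fs)
    return f[np.argmax(p)]
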