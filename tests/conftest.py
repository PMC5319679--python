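import numpy as np
import pytest

from posturofall.boards import BoardForceTrace, BoardGeometry, CoPTrace


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def geometry():
    return BoardGeometry(length_ap=433.0, width_ml=228.0)


def random_force_trace(rng, n=120, fs=100.0, base=200.0):
    """Strictly positive 4-channel forces around a realistic per-board load."""
    forces = base + 30.0 * rng.random((n, 4))
    return BoardForceTrace(forces=forces, fs=fs)


def random_cop_trace(rng, n=300, fs=100.0, scale=5.0):
    return CoPTrace(
        ap=scale * rng.standard_normal(n).cumsum() / np.sqrt(n),
        ml=scale * rng.standard_normal(n).cumsum() / np.sqrt(n),
        fs=fs,
    )


def sinusoid_trace(amplitude=10.0, freq=1.0, fs=100.0, duration=30.0):
    t = np.arange(int(round(duration * fs))) / fs
    ap = amplitude * np.sin(2 * np.pi * freq * t)
    return CoPTrace(ap=ap, ml=np.zeros_like(ap), fs=fs)
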