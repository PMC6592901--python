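import numpy as np
import pytest

from sensorydrive.audiogram_metrics import Audiogram


@pytest.fixture
def octave_audiogram():
    """Typical U-shaped audiogram on an octave grid, best frequency 8 kHz."""
    f = np.array([0.25, 0.5, 1, 2, 4, 8, 16, 32, 64], dtype=float)
    t = np.array([60, 45, 32, 20, 12, 8, 14, 30, 55], dtype=float)
    return Audiogram(species="testsp", frequencies_khz=f, thresholds_db=t)


@pytest.fixture
def two_point_audiogram():
    """The two-point interpolation example: (16 kHz, 10 dB), (32 kHz, 30 dB)."""
    return Audiogram(
        species="pair",
        frequencies_khz=np.array([16.0, 32.0]),
        thresholds_db=np.array([10.0, 30.0]),
    )


def flat_audiogram(level_db: float = 20.0, species: str = "flat") -> Audiogram:
    f = np.array([0.5, 1, 2, 4, 8, 16, 32], dtype=float)
    return Audiogram(
        species=species, frequencies_khz=f, thresholds_db=np.full(f.size, level_db)
    )


@pytest.fixture
def flat20():
    return flat_audiogram(20.0)
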