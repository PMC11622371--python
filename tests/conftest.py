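import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_spectrumset():
    """5-peak, 4-spectrum counts table with two classes."""
    from specdiff import PeakList, SpectrumSet

    peaks = PeakList(np.array([26.0, 48.0, 63.96, 80.0, 101.0]))
    intensities = np.array([
        [900.0, 120.0, 40.0, 15.0, 7.0],
        [880.0, 130.0, 38.0, 14.0, 9.0],
        [910.0, 60.0, 80.0, 16.0, 8.0],
        [905.0, 55.0, 85.0, 13.0, 6.0],
    ])
    return SpectrumSet(
        peaks=peaks,
        intensities=intensities,
        labels=("initial", "initial", "processed", "processed"),
    )
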