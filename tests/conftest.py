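import warnings

import pytest

from liporelax import SpectrometerConfig
from liporelax.reference import characterization_records


@pytest.fixture(scope="session")
def config() -> SpectrometerConfig:
    """Default spectrometer: 30.2 MHz proton, 5 G spin-lock, 303 K."""
    return SpectrometerConfig()


@pytest.fixture()
def char_records():
    """The 16-row characterization table, verbatim (one size outlier intact)."""
    return characterization_records()


@pytest.fixture(autouse=True)
def _quiet_regime_warning():
    """Nanosecond correlation times at 30.2 MHz always trip the slow-motion
    diagnostic; silence it so tests assert on values, not noise."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*fast-motion regime.*")
        yield
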