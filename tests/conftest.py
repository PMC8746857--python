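import numpy as np
import pytest
from hypothesis import settings

import oilscreen as osn
from oilscreen.screen import OilScreen

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def olive():
    return osn.make_oil("olive")


@pytest.fixture(scope="session")
def chemistry():
    return osn.load_chemistry()


@pytest.fixture(scope="session")
def acq_quiet():
    """Fast, noise-free acquisition for deterministic oracles."""
    return osn.AcquisitionParams(n_points=8192, noise_sigma=0.0,
                                 shift_jitter_sigma=0.0)


@pytest.fixture(scope="session")
def acq_fast():
    """Fast acquisition with the default noise and jitter."""
    return osn.AcquisitionParams(n_points=8192)


@pytest.fixture(scope="session")
def quiet_screen(acq_quiet):
    return OilScreen(acq=acq_quiet)


@pytest.fixture(scope="session")
def fast_screen(acq_fast):
    return OilScreen(acq=acq_fast)


@pytest.fixture(scope="session")
def olive_spectrum_quiet(olive, acq_quiet):
    """Fully processed zero-noise olive spectrum (8192 points)."""
    return osn.render_spectrum(olive, acq=acq_quiet,
                               rng=np.random.default_rng(0))
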