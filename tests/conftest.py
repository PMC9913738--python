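import numpy as np
import pytest

import lmdlipidomics as L


@pytest.fixture(scope="session")
def registry():
    return L.default_registry()


@pytest.fixture(scope="session")
def standards():
    return L.StandardSet.default()


@pytest.fixture
def noiseless_acq():
    """Acquisition with every stochastic element switched off."""
    return L.AcquisitionSpec(ppm_sd=0.0, intensity_cv=0.0, noise_floor=1e-9)


@pytest.fixture(scope="session")
def liver_profile():
    return L.make_lipidome(seed=3)


@pytest.fixture
def noiseless_spot(liver_profile, noiseless_acq):
    return L.simulate_spot(
        liver_profile, L.SpotSpec(30_000.0), acq=noiseless_acq, sample_id="spot0"
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230428)
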