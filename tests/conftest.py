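import numpy as np
import pytest

from redoxmap import DEFAULT_CALIBRATION, SimScenario, make_fluorophore_model


@pytest.fixture(scope="session")
def calib():
    """Reference CA1 calibration triple."""
    return DEFAULT_CALIBRATION


@pytest.fixture(scope="session")
def model(calib):
    """Forward fluorophore model derived from the reference calibration."""
    return make_fluorophore_model(calib)


@pytest.fixture
def noise_free_scenario():
    """Scenario with every noise source disabled (float images)."""
    return SimScenario(
        photon_scale=np.inf,
        background=0.0,
        neuropil_level=0.0,
        read_noise_sd=0.0,
        cells_per_field=5,
    )


@pytest.fixture
def noisy_scenario():
    """Default photon-limited acquisition conditions."""
    return SimScenario()
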