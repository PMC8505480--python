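import numpy as np
import pytest

from melflicker.colorimetry import synthetic_sensitivities
from melflicker.stimulus_design import solve_background_pair, solve_flicker_modulation
from melflicker.synthetic_data import make_synthetic_device


@pytest.fixture(scope="session")
def sens():
    return synthetic_sensitivities()


@pytest.fixture(scope="session")
def device(sens):
    return make_synthetic_device(wavelengths=sens.wavelengths, seed=0)


@pytest.fixture(scope="session")
def background_pair(device, sens):
    """Cone-silenced 350%-melanopic background pair on the synthetic device."""
    return solve_background_pair(device, sens, target_mel_contrast=3.5)


@pytest.fixture(scope="session")
def flicker_spec(device, sens, background_pair):
    low, _ = background_pair
    return solve_flicker_modulation(device, sens, low, lms_target=0.05)
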