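import numpy as np
import pytest

from simrestore import synth


@pytest.fixture(scope="session")
def optics128():
    return synth.make_optical_model(shape=(128, 128))


@pytest.fixture(scope="session")
def noise_free_acq():
    return synth.AcquisitionSettings(shot_noise=False, read_noise_sd=0.0)


@pytest.fixture(scope="session")
def filament_scene():
    return synth.generate_scene("filament", 128, 128, seed=1)


@pytest.fixture(scope="session")
def clean_stack(filament_scene, optics128, noise_free_acq):
    """Noise-free 15-frame stack of a filament scene."""
    return synth.simulate_raw_stack(filament_scene, optics128, noise_free_acq)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
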