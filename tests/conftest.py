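import numpy as np
import pytest

from eegisc import Recording, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """A 4-channel (3 EEG + 1 EOG) recording of pink-ish noise at 125 Hz."""
    t = 1250
    data = rng.standard_normal((4, t))
    return Recording(
        subject_id="S001",
        condition="Wimpy",
        fs=125.0,
        data=data,
        channel_names=["E1", "E2", "E3", "EOG1"],
        channel_roles=["EEG", "EEG", "EEG", "EOG"],
        age=12.0,
        sex="female",
    )


@pytest.fixture
def tiny_sim_cfg():
    """Desk-scale simulator config for fast end-to-end tests."""
    return SimConfig(n_subjects=8, n_channels=8, duration_s=24.0, seed=99)
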