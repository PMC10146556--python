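import numpy as np
import pytest

from cardiovar.preprocess import validate_beats
from cardiovar.simulate import condition_preset, generate_recording, recovery_preset


@pytest.fixture(scope="session")
def preset_recording():
    """A 600-beat ambulatory-normoxia recording (fixed seed)."""
    return generate_recording(condition_preset("ambulatory_normoxia", seed=7),
                              condition_label="ambulatory_normoxia",
                              subject_id="s00")


@pytest.fixture(scope="session")
def clean_preset(preset_recording):
    return validate_beats(preset_recording)


@pytest.fixture(scope="session")
def recovery_recording():
    """Low-noise recording with arterial gain 20 ms/mmHg, 700 beats."""
    return generate_recording(recovery_preset(20.0, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
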