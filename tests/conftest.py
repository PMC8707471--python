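import numpy as np
import pytest

from drivevitals.synth import EcgProfile, gen_ecg


@pytest.fixture(scope="session")
def clean_ecg_75():
    """30 s of clean normal ECG at 75 bpm, 500 Hz."""
    return gen_ecg(EcgProfile.for_class("normal", 75.0), 30.0, 500.0, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
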