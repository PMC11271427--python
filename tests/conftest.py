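import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from bionicgait.controller import BioTorqueModel
from bionicgait.decoder import DecoderCalibration
from bionicgait.emg import design_bandpass


@pytest.fixture(scope="session")
def taps():
    """Reference band-pass taps at 2 kHz (expensive to design; shared)."""
    return design_bandpass(2000.0)


@pytest.fixture(scope="session")
def unit_calib():
    """Calibration from the clean (1,0)/(0,1) DF/PF plateau pair."""
    return DecoderCalibration(10.0, 20.0, 10.0, 20.0)


@pytest.fixture(scope="session")
def bio_model():
    return BioTorqueModel()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
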