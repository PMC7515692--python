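import numpy as np
import pytest

from massphot.models import AcquisitionWindow, ContrastModel, KineticsModel


@pytest.fixture
def window():
    return AcquisitionWindow(t0=15.0, t_final=135.0)


@pytest.fixture
def contrast_model():
    return ContrastModel()


@pytest.fixture
def kinetics_model():
    return KineticsModel(alpha=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
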