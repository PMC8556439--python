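import numpy as np
import pytest

from comxdyn.comx_model import ComXModelParams
from comxdyn.synthgen import SynthConfig


@pytest.fixture
def midpoint_params():
    """Kinetic parameters at the midpoint of the study bounds."""
    return ComXModelParams.midpoint()


@pytest.fixture
def logistic_biomass():
    """The reference-process logistic biomass curve (0.031 -> 5.4 g/L)."""
    return SynthConfig().biomass_curve()


@pytest.fixture
def hour_grid():
    return np.linspace(0.0, 48.0, 97)
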