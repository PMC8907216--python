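import numpy as np
import pytest

from nanotopo.calibration import build_axial_lut
from nanotopo.synthdata import OpticalModel, simulate_calibration_scan


@pytest.fixture(scope="session")
def optical_model():
    return OpticalModel()


@pytest.fixture(scope="session")
def noiseless_lut(optical_model):
    """Axial LUT built from a noiseless default calibration scan."""
    scan, _ = simulate_calibration_scan(optical_model, noise="none", seed=1)
    return build_axial_lut(scan)
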