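import numpy as np
import pytest

from mitoquant.synthdata import ImageTruth, ParticleSpec, TraceTruth

FULL_FLOWS = {
    "Ce": 10.0,
    "CI_L": 8.0,
    "CI_P": 30.0,
    "CIcytc": 31.0,
    "CIplusCII_P": 50.0,
    "CII_P": 42.0,
    "CII_E": 60.0,
}

FULL_INJECTIONS = {
    "digitonin": 120.0,
    "pyruvate": 240.0,
    "malate": 300.0,
    "ADP": 420.0,
    "cytc": 540.0,
    "succinate": 660.0,
    "rotenone": 780.0,
    "FCCP": 900.0,
}


@pytest.fixture
def suit_truth():
    return TraceTruth(state_flows=dict(FULL_FLOWS), injection_times=dict(FULL_INJECTIONS))


@pytest.fixture
def single_particle_truth():
    """One 25-px disk (1.0 µm² at 0.2 µm/px) centered in a square cell mask."""
    cell = np.zeros((200, 200), np.int32)
    cell[40:160, 40:160] = 1
    return ImageTruth(
        cell_masks=cell,
        particles=[ParticleSpec(center=(100, 100), area_um2=1.0)],
        pixel_size=0.2,
    )
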