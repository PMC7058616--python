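from dataclasses import replace

import pytest

from viffi import InstrumentDesign, SensorNoise, standard_modes


@pytest.fixture(scope="session")
def design():
    """The reference instrument design (all defaults)."""
    return InstrumentDesign()


@pytest.fixture(scope="session")
def crop_design(design):
    """Small-FOV variant (52 x 52 µm) for fast per-cell renders."""
    return replace(design, L_x=1.04, N_y=160)


@pytest.fixture(scope="session")
def modes():
    return standard_modes()


@pytest.fixture(scope="session")
def noise():
    return SensorNoise()
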