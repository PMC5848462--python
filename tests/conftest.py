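import numpy as np
import pytest

from cafasim import BloodModel, make_stenotic_geometry


@pytest.fixture
def blood():
    return BloodModel()


@pytest.fixture
def uniform_tube():
    """Straight 2 mm-radius tube, 10 cm long (degree-0 geometry)."""
    return make_stenotic_geometry(2e-3, 0.0, 0.05, 0.02, 0.10, 400)


@pytest.fixture
def stenotic_70():
    """2.5 mm vessel with a 70% NASCET cosine stenosis centered at 2 cm."""
    return make_stenotic_geometry(2.5e-3, 0.70, 0.02, 0.02, 0.10, 800)
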