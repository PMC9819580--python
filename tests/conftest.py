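import numpy as np
import pytest

from usbwx.phantom_sim import PulseSpec, make_scatterer_field, simulate_rf
from usbwx.workflows import simulate_paired_dataset


@pytest.fixture(scope="session")
def pulse():
    return PulseSpec()


@pytest.fixture(scope="session")
def speckle_rf(pulse):
    """A dense random speckle RF image, 128 x 128."""
    field = make_scatterer_field((128, 128), density=0.6, seed=11)
    return simulate_rf(field, pulse)


@pytest.fixture(scope="session")
def small_pairs():
    """Four simulated 128 x 128 pairs at 20% fractional bandwidth."""
    return simulate_paired_dataset(4, (128, 128), fraction=0.2, seed=5)
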