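import logging

import numpy as np
import pytest

from holorec.optics import ComplexField, OpticalConfig

# propagation kernel undersampling warnings are expected at these grid sizes
logging.getLogger("holorec.optics").setLevel(logging.ERROR)


@pytest.fixture
def cfg():
    """Default optics, padded propagation."""
    return OpticalConfig()


@pytest.fixture
def cfg_periodic():
    """Unpadded (periodic) propagation: exactly unitary, self-consistent."""
    return OpticalConfig(pad_factor=1)


@pytest.fixture
def cfg_keep():
    """Periodic propagation with evanescent pass-through (round-trip tests)."""
    return OpticalConfig(pad_factor=1, evanescent_policy="keep")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_field(rng, cfg_periodic):
    vals = rng.standard_normal((64, 64)) + 1j * rng.standard_normal((64, 64))
    return ComplexField(values=vals, config=cfg_periodic, z=0.0)
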