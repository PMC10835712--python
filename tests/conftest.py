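import numpy as np
import pytest

from sdep.double_layer import ChargedInterface, IonicMedium
from sdep.sphere_interaction import DielectricSphere


@pytest.fixture
def medium01() -> IonicMedium:
    """Physiological 0.1 M 1:1 electrolyte at ambient conditions."""
    return IonicMedium(0.1)


@pytest.fixture
def dpps(medium01) -> ChargedInterface:
    """Fully charged PS-like plane, |sigma| = 0.35 C/m²."""
    return ChargedInterface(0.35)


@pytest.fixture
def peg600() -> DielectricSphere:
    """PEG600 as a low-permittivity sphere, R_h = 7 Å."""
    return DielectricSphere(7.0, 10.0, 600)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240116)
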