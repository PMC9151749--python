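import numpy as np
import pytest

from nirsox.optics import (
    ChromophoreSpectra,
    MUSCLE_NIR,
    MUSCLE_RED,
    ProbeGeometry,
    ScatteringModel,
)


@pytest.fixture(scope="session")
def spectra():
    return ChromophoreSpectra()


@pytest.fixture(scope="session")
def geom():
    return ProbeGeometry()


@pytest.fixture(scope="session")
def scattering():
    # k_scale chosen so mu_s'(850 nm) equals the muscle value 6.67 /cm
    return ScatteringModel(k_scale=13.38)


@pytest.fixture(scope="session")
def muscle_red():
    return MUSCLE_RED


@pytest.fixture(scope="session")
def muscle_nir():
    return MUSCLE_NIR


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
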