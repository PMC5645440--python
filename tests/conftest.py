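import numpy as np
import pytest

from phycoscope import make_reference_spectra, simulate_scene
from phycoscope.synthetic import SceneGeometry


@pytest.fixture(scope="session")
def ref():
    """Default six-component reference spectra."""
    return make_reference_spectra()


@pytest.fixture(scope="session")
def small_geometry():
    """Reduced frame for fast unit tests."""
    return SceneGeometry(shape=(96, 96))


@pytest.fixture(scope="session")
def control_scene(ref):
    """One default-geometry control scene with noise and ground truth."""
    return simulate_scene("T0+N", n_cells=20, seed=7, reference=ref)


@pytest.fixture(scope="session")
def small_scene(ref, small_geometry):
    """Small control scene (6 cells, 96×96) for cheap tests."""
    return simulate_scene(
        "T0+N", n_cells=6, seed=7, geometry=small_geometry, reference=ref
    )
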