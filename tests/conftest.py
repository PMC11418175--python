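import numpy as np
import pytest

from shrimpglass.em_solver import Scene, SolverConfig


@pytest.fixture(scope="session")
def fast_planar_config():
    """Coarse but stability-valid solver settings for planar test scenes."""
    return SolverConfig(resolution_nm=20.0, polarization="s", max_steps=30_000)


@pytest.fixture(scope="session")
def slab_scene():
    """The control geometry: 5 µm chitin slab in seawater."""
    return Scene(lateral_um=0.2, matrix_n=1.34, layers=((5.0, 1.57),))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
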