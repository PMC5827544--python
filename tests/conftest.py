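import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import emt4d as e

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_spec():
    """Reduced phantom keeping unit tests fast (full default grid is used in
    the acceptance protocol)."""
    return e.PhantomSpec(image_shape=(32, 32, 20), seed=7)


@pytest.fixture(scope="session")
def small_alignment(small_spec):
    return e.GridAlignment(
        image_grid=small_spec.image_grid,
        dose_grid=small_spec.dose_grid,
        ratio=small_spec.grid_ratio,
    )


@pytest.fixture(scope="session")
def compressing_phase(small_spec):
    """A phase with maximal superior-inferior compression (s = 1)."""
    i = small_spec.n_phases // 4  # sin(2 pi i / P) = 1 for P = 10, i = 2.5 -> use 2
    image, dvf = e.generate_phase(small_spec, i)
    return i, image, dvf


@pytest.fixture(scope="session")
def compiled_tables(small_spec, compressing_phase):
    _, _, dvf = compressing_phase
    push = e.compile_push(dvf, small_spec.dose_grid)
    pull = e.compile_pull(push, small_spec.dose_grid)
    unified = e.compile_unified(push, small_spec.dose_grid)
    return push, pull, unified


@pytest.fixture(scope="session")
def phase_inputs(small_spec, compressing_phase):
    i, image, _ = compressing_phase
    mass = e.image_voxel_mass(e.hu_to_density(image))
    dose = e.generate_tick_dose(small_spec, i)
    return dose, mass


def identity_grid(shape=(6, 6, 6), spacing=(1.0, 1.0, 1.0)):
    return e.Grid3D(origin=(0.0, 0.0, 0.0), spacing=spacing, shape=shape)


def zero_dvf(grid):
    return e.DisplacementField(
        grid=grid, vectors=np.zeros(grid.shape + (3,))
    )


@pytest.fixture
def unit_grid():
    return identity_grid()
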