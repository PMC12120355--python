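import numpy as np
import pytest

from cherensim.phantom import Tissue, VoxelGrid, extract_surface_mesh
from cherensim.properties import default_optical_tables, default_radiological_tables


@pytest.fixture(scope="session")
def optical_tables():
    return default_optical_tables()


@pytest.fixture(scope="session")
def radiological_tables():
    return default_radiological_tables()


def homogeneous_grid(tissue, shape, spacing=1.0, density=None):
    """Uniform single-tissue grid centered on the origin."""
    from cherensim.phantom import DEFAULT_DENSITIES

    shape = (shape,) * 3 if np.isscalar(shape) else tuple(shape)
    sp = (spacing,) * 3 if np.isscalar(spacing) else tuple(spacing)
    rho = density if density is not None else DEFAULT_DENSITIES[tissue]
    labels = np.full(shape, tissue, dtype=np.uint8)
    dens = np.full(shape, rho)
    origin = tuple(-(n - 1) / 2 * s for n, s in zip(shape, sp))
    return VoxelGrid(tissue=labels, density=dens, spacing=sp, origin=origin)


def uniform_optical_tables(mu_a, mu_s, g, n):
    """Tables with identical constant properties for every tissue label."""
    tab = default_optical_tables()
    for t in tab.mu_a:
        tab.mu_a[t][:] = mu_a
        tab.mu_s[t][:] = mu_s
        tab.g[t][:] = g
        tab.n[t][:] = n
    return tab


def pure_photoelectric_tables(mu_per_mm):
    """Radiological tables with zero Compton and a flat photoelectric mu."""
    rad = default_radiological_tables()
    for t in rad.mu_compton:
        rad.mu_compton[t][:] = 0.0
        rad.mu_photoelectric[t][:] = mu_per_mm
    return rad


@pytest.fixture(scope="session")
def water_block():
    grid = homogeneous_grid(Tissue.WATER, (41, 41, 61), spacing=1.0, density=1.0)
    return grid, extract_surface_mesh(grid)
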