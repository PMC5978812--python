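import numpy as np
import pytest

from epivertex.dynamics import generate_monolayer
from epivertex.mechanics import ModelParams
from epivertex.tessellation import hexagonal_lattice, matern_ii_points, voronoi_network


@pytest.fixture(scope="session")
def params_iia():
    """Interior region-IIa parameters used for most mechanics tests."""
    return ModelParams(lam=-0.2, gam=0.1)


@pytest.fixture(scope="session")
def relaxed_monolayer(params_iia):
    """100-cell zero-load equilibrium monolayer (shared, do not mutate)."""
    return generate_monolayer(params_iia, 100, seed=2)


@pytest.fixture(scope="session")
def zero_load_200():
    """200-cell zero-load monolayer at (-0.1, 0.1) (shared, do not mutate)."""
    return generate_monolayer(ModelParams(lam=-0.1, gam=0.1), 200, seed=7)


@pytest.fixture(scope="session")
def hex_lattice():
    return hexagonal_lattice(1.0, 4, 4)


@pytest.fixture(scope="session")
def small_voronoi():
    """Unrelaxed 50-cell periodic Voronoi network."""
    return voronoi_network(matern_ii_points(7.0, 50, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_simple_polygon(rng, n=None):
    """Star-shaped random polygon: sorted angles, random radii (always
    simple)."""
    if n is None:
        n = int(rng.integers(4, 9))
    theta = np.sort(rng.uniform(0, 2 * np.pi, size=n))
    # enforce distinct angles so no zero-length edges
    while np.any(np.diff(theta) < 1e-3):
        theta = np.sort(rng.uniform(0, 2 * np.pi, size=n))
    r = rng.uniform(0.5, 1.5, size=n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])
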