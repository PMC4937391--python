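import numpy as np
import pytest

from retractsim import OgdenPronyMaterial
from retractsim.mesh import CrackGeometry, build_hex_mesh, classify_and_enrich


@pytest.fixture(scope="session")
def material():
    """Swine-brain Ogden/Prony parameters used throughout."""
    return OgdenPronyMaterial()


@pytest.fixture(scope="session")
def cube_mesh():
    """20 mm solid cube, 4x4x4 hexes of 5 mm."""
    return build_hex_mesh(np.ones((20, 20, 20), bool), 1.0, 5.0)


@pytest.fixture(scope="session")
def cube_enriched(cube_mesh):
    """Cube bisected by a through-going crack (x = 10.3)."""
    crack = CrackGeometry(point=[10.3, 0.0, 0.0], normal=[1, 0, 0])
    return classify_and_enrich(cube_mesh, crack)


@pytest.fixture(scope="session")
def two_elem_cut():
    """Two 5 mm hexes in a row, the first cut by a through crack."""
    mesh = build_hex_mesh(np.ones((10, 5, 5), bool), 1.0, 5.0)
    crack = CrackGeometry(point=[3.7, 0.0, 0.0], normal=[1, 0, 0])
    return classify_and_enrich(mesh, crack)


@pytest.fixture(scope="session")
def small_phantom():
    """Down-scaled phantom for fast unit tests (full scale in acceptance)."""
    from retractsim.phantom import PhantomConfig, generate_phantom
    cfg = PhantomConfig(semi_axes=(16.0, 13.0, 11.0), n_beads=6,
                        blade_depth=9.0, retractor_width=8.0,
                        opening_right=2.7, opening_left=1.4, seed=3)
    return generate_phantom(cfg)
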