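import numpy as np
import pytest

import poregraph as pg


@pytest.fixture(scope="session")
def cube3():
    """3x3x3 all-pore cube graph and Laplacian."""
    image = pg.generate_full_cube((3, 3, 3))
    graph = pg.build_voxel_graph(image)
    return graph, pg.laplacian(graph)


@pytest.fixture(scope="session")
def two_node():
    """Two face-adjacent pore voxels."""
    image = pg.generate_chain_image(2)
    graph = pg.build_voxel_graph(image)
    return graph, pg.laplacian(graph)


@pytest.fixture(scope="session")
def packing16():
    """Small connected ball packing on a 16^3 grid (seeded)."""
    spec = pg.SynthGeometrySpec(
        dims=(16, 16, 16), n_balls=12, radius_range=(2.5, 4.0), seed=42
    )
    balls, image = pg.generate_ball_packing(spec)
    graph = pg.build_voxel_graph(image)
    return balls, image, graph, pg.laplacian(graph)


@pytest.fixture(scope="session")
def packing48():
    """Desk-scale connected ball packing: ~20 balls on a 48^3 grid (seeded)."""
    spec = pg.SynthGeometrySpec(
        dims=(48, 48, 48), n_balls=20, radius_range=(3.0, 6.0), seed=7
    )
    balls, image = pg.generate_ball_packing(spec)
    graph = pg.build_voxel_graph(image)
    return balls, image, graph, pg.laplacian(graph)


def random_binary_image(rng: np.random.Generator, dims, porosity=0.5):
    vals = (rng.random(dims) > porosity).astype(np.uint8)
    return pg.BinaryImage3D(vals)
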