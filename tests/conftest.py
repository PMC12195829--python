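import numpy as np
import pytest

from vasctrans.geometry import (
    GeometryRecipe,
    TissueModel,
    VesselNetwork,
    generate_geometry,
)


@pytest.fixture(scope="session")
def small_geometry():
    """Reduced vascularized-tissue geometry shared by solver tests."""
    recipe = GeometryRecipe(target_3d_elements=900, n_vessel_segments=50, seed=7)
    network, model = generate_geometry(recipe)
    return network, model


@pytest.fixture(scope="session")
def default_geometry():
    """The default brain-like recipe (~5000 tets, 200 segments)."""
    network, model = generate_geometry(GeometryRecipe(seed=11))
    return network, model


def unit_box_mesh(n: int = 1) -> TissueModel:
    """Unit box [0,1]^3 meshed with 6*n^3 tets."""
    from vasctrans.geometry import generate_tissue_mesh

    recipe = GeometryRecipe(
        domain_shape="box",
        dimensions=(1.0, 1.0, 1.0),
        target_3d_elements=6 * n**3,
        seed=0,
    )
    return generate_tissue_mesh(recipe)


def single_tet_model(rv: float | None = 0.5) -> TissueModel:
    """One reference tetrahedron with a uniform capillary fraction."""
    points = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    cells = np.array([[0, 1, 2, 3]])
    model = TissueModel(points=points, cells=cells)
    if rv is not None:
        model.rv_field = np.full(1, rv)
    return model


def straight_network(p0, p1, radius=0.01, kind="capillary") -> VesselNetwork:
    """Two-node single-segment network from p0 to p1."""
    return VesselNetwork(
        nodes=np.array([p0, p1], dtype=float),
        segments=np.array([[0, 1]]),
        radii=np.array([radius]),
        kinds=np.array([kind]),
        inlet_nodes=np.array([0]),
        outlet_nodes=np.array([1]),
    )
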