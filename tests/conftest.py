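"""Shared fixtures: coarse meshes and solved fields reused across tests.

Coarse discretisations (h = 0.8-1.6 mm) are used wherever a test checks an
invariant rather than an accuracy figure; accuracy assertions build their
own meshes at the resolution they state.
"""

import numpy as np
import pytest

from aaa_ilt.elasticity import LoadCase, Material, solve_linear
from aaa_ilt.geometry import SliceGeometry
from aaa_ilt.mesh import build_mesh

WALL = Material(1.0e6, 0.45)
THROMBUS = Material(1.0e5, 0.45)
MATERIALS = {"wall": WALL, "thrombus": THROMBUS}


@pytest.fixture(scope="session")
def materials():
    return MATERIALS


@pytest.fixture(scope="session")
def annulus_geometry():
    """Thrombus-free wall annulus (lumen radius = cavity radius)."""
    return SliceGeometry()


@pytest.fixture(scope="session")
def two_layer_geometry():
    """Central thrombus with the 17 mm lumen diameter of the base case."""
    return SliceGeometry(lumen_radius=8.5)


@pytest.fixture(scope="session")
def coarse_two_layer_mesh(two_layer_geometry):
    return build_mesh(two_layer_geometry, h_tissue=0.8)


@pytest.fixture(scope="session")
def free_loads():
    """Default pressures, no spine (for axisymmetric verification cases)."""
    return LoadCase(spine_contact="none")


@pytest.fixture(scope="session")
def coarse_two_layer_solution(coarse_two_layer_mesh, free_loads):
    return solve_linear(coarse_two_layer_mesh, MATERIALS, free_loads)


def radial_component(mesh, u):
    r = np.linalg.norm(mesh.nodes, axis=1)
    return np.einsum("ij,ij->i", u, mesh.nodes / np.maximum(r, 1e-12)[:, None]), r
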