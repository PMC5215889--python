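import numpy as np
import pytest

from meshacc.mesh import TriangleMesh
from meshacc.phantom import PhantomSpec, flat_patch, generate_phantom


@pytest.fixture(scope="session")
def phantom_small():
    """A 40x40 face phantom with its landmark set (shared, do not mutate)."""
    return generate_phantom(PhantomSpec(resolution=(40, 40)))


@pytest.fixture(scope="session")
def phantom_mesh(phantom_small):
    return phantom_small[0]


@pytest.fixture(scope="session")
def phantom_landmarks(phantom_small):
    return phantom_small[1]


@pytest.fixture()
def tiny_mesh():
    """A fresh two-triangle square in the z=0 plane."""
    return TriangleMesh(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]],
        [[0, 1, 2], [0, 2, 3]],
    )


@pytest.fixture(scope="session")
def patch_flat():
    """A 30x30 flat grid at z=0, 5 mm spacing (shared, do not mutate)."""
    return flat_patch(30, 5.0)


def submesh_first_triangles(mesh: TriangleMesh, n: int) -> TriangleMesh:
    """The first n triangles of a mesh, vertices compacted."""
    keep = np.zeros(mesh.n_triangles, dtype=bool)
    keep[:n] = True
    tris = mesh.triangles[keep]
    used = np.zeros(mesh.n_vertices, dtype=bool)
    used[tris.ravel()] = True
    remap = np.cumsum(used) - 1
    return TriangleMesh(mesh.vertices[used], remap[tris])
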