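import numpy as np
import pytest
import trimesh

from atriaflow import SurfaceMesh


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_cube():
    """Unit cube surface: 8 vertices, 12 triangles, total area 6."""
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return SurfaceMesh(np.asarray(box.vertices, float),
                       np.asarray(box.faces, np.int64))


def icosphere(subdivisions=3, radius=1.0) -> SurfaceMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(np.asarray(ico.vertices, float),
                       np.asarray(ico.faces, np.int64))


@pytest.fixture
def sphere3():
    return icosphere(subdivisions=3)


@pytest.fixture
def small_patch():
    """Two coplanar triangles covering the unit square in z = 0."""
    verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
    return SurfaceMesh(verts, np.array([[0, 1, 2], [1, 3, 2]]))
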