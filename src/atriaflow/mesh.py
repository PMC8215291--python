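"""Triangulated surface meshes and their basic geometric quantities.

Everything downstream (fibrosis mapping, wall-shear metrics, burden
statistics) lives on a :class:`SurfaceMesh`: a triangle soup with named
per-vertex and per-triangle fields.  Coordinates are millimetres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

__all__ = ["SurfaceMesh", "AreaWeights", "compute_area_weights",
           "triangle_normals", "vertex_normals", "enclosed_volume"]


@dataclass
class SurfaceMesh:
    """A triangulated surface with named per-vertex / per-triangle fields.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    triangles : (m, 3) int array of 0-based vertex indices
    vertex_data : mapping of field name -> (n,) or (n, 3) array
    triangle_data : mapping of field name -> (m,) or (m, 3) array
    """

    vertices: np.ndarray
    triangles: np.ndarray
    vertex_data: dict = field(default_factory=dict)
    triangle_data: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.triangles.size and (self.triangles.ndim != 2
                                    or self.triangles.shape[1] != 3):
            raise ValueError("triangles must be an (m, 3) array")
        self.triangles = self.triangles.reshape(-1, 3)
        if self.triangles.size:
            if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
                raise ValueError("triangle index out of range")
        for name, arr in {**self.vertex_data}.items():
            arr = np.asarray(arr)
            if arr.shape[0] != self.n_vertices:
                raise ValueError(f"vertex field {name!r} has wrong length")
            self.vertex_data[name] = arr
        for name, arr in {**self.triangle_data}.items():
            arr = np.asarray(arr)
            if arr.shape[0] != self.n_triangles:
                raise ValueError(f"triangle field {name!r} has wrong length")
            self.triangle_data[name] = arr

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def centroid(self) -> np.ndarray:
        """Arithmetic mean of the vertex coordinates (mm)."""
        return self.vertices.mean(axis=0)

    def triangle_corners(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        v = self.vertices
        t = self.triangles
        return v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.triangles.copy(),
                           {k: np.array(v) for k, v in self.vertex_data.items()},
                           {k: np.array(v) for k, v in self.triangle_data.items()})


@dataclass
class AreaWeights:
    """Per-vertex and per-triangle areas (mm²), exactly conservative.

    The vertex area is one third of the summed areas of its incident
    triangles, so ``sum(per_vertex_area) == sum(per_triangle_area)`` by
    construction.  Conservation matters here because burden fractions are
    ratios of these areas; curvature-accurate (Voronoi) weights are not
    needed for that and would break exact conservation.
    """

    per_vertex_area: np.ndarray
    per_triangle_area: np.ndarray
    total_area: float


def _triangle_area_vectors(mesh: SurfaceMesh) -> np.ndarray:
    """Unnormalized triangle normals: 0.5 * (b - a) x (c - a)."""
    a, b, c = mesh.triangle_corners()
    return 0.5 * np.cross(b - a, c - a)


def compute_area_weights(mesh: SurfaceMesh) -> AreaWeights:
    """Triangle areas by the cross-product formula and 1/3-rule vertex areas."""
    tri_area = np.linalg.norm(_triangle_area_vectors(mesh), axis=1)
    n_zero = int(np.count_nonzero(tri_area == 0.0))
    if n_zero:
        log.warning("%d zero-area triangle(s) contribute no area", n_zero)
    vert_area = np.zeros(mesh.n_vertices)
    np.add.at(vert_area, mesh.triangles.ravel(),
              np.repeat(tri_area / 3.0, 3))
    return AreaWeights(per_vertex_area=vert_area,
                       per_triangle_area=tri_area,
                       total_area=float(tri_area.sum()))


def enclosed_volume(mesh: SurfaceMesh) -> float:
    """Signed volume enclosed by a closed surface (divergence theorem).

    Positive for outward-oriented triangles; mm³.
    """
    a, b, c = mesh.triangle_corners()
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def triangle_normals(mesh: SurfaceMesh) -> np.ndarray:
    """Unit triangle normals; zero for degenerate triangles."""
    av = _triangle_area_vectors(mesh)
    norm = np.linalg.norm(av, axis=1)
    out = np.zeros_like(av)
    ok = norm > 0
    out[ok] = av[ok] / norm[ok, None]
    return out


def vertex_normals(mesh: SurfaceMesh, orientation: str = "outward",
                   reference_point: np.ndarray | None = None) -> np.ndarray:
    """Angle-weighted per-vertex unit normals with a chosen orientation.

    Each vertex normal is the average of its incident triangle normals
    weighted by the corner angle, then normalized.  Orientation is resolved
    per vertex against an interior reference point (the mesh centroid by
    default): ``inward`` normals point toward the reference, ``outward``
    away from it.  Atrial walls are close enough to star-shaped for this;
    pass ``reference_point`` for anything else.

    Isolated vertices (no incident triangle) get a zero normal and a
    logged count; callers exclude them downstream.
    """
    if orientation not in ("inward", "outward"):
        raise ValueError("orientation must be 'inward' or 'outward'")
    ref = mesh.centroid if reference_point is None else np.asarray(reference_point, float)

    a, b, c = mesh.triangle_corners()
    fn = triangle_normals(mesh)

    def corner_angle(p, q, r):
        u, v = q - p, r - p
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        denom = np.where(nu * nv > 0, nu * nv, 1.0)
        cosang = np.clip(np.einsum("ij,ij->i", u, v) / denom, -1.0, 1.0)
        return np.arccos(cosang)

    angles = np.stack([corner_angle(a, b, c),
                       corner_angle(b, c, a),
                       corner_angle(c, a, b)], axis=1)  # (m, 3)

    acc = np.zeros((mesh.n_vertices, 3))
    np.add.at(acc, mesh.triangles.ravel(),
              (angles[:, :, None] * fn[:, None, :]).reshape(-1, 3))

    norm = np.linalg.norm(acc, axis=1)
    isolated = np.zeros(mesh.n_vertices, dtype=bool)
    if mesh.triangles.size:
        incident = np.zeros(mesh.n_vertices, dtype=bool)
        incident[np.unique(mesh.triangles)] = True
        isolated = ~incident
    else:
        isolated[:] = True
    if isolated.any():
        log.warning("%d isolated vertex/vertices: normal set to zero",
                    int(isolated.sum()))

    out = np.zeros_like(acc)
    ok = (norm > 0) & ~isolated
    out[ok] = acc[ok] / norm[ok, None]

    # resolve orientation per vertex against the reference point
    to_ref = ref[None, :] - mesh.vertices
    inwardness = np.einsum("ij,ij->i", out, to_ref)
    want_positive = orientation == "inward"
    flip = (inwardness < 0) if want_positive else (inwardness > 0)
    out[flip & ok] *= -1.0
    return out
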