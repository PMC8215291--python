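"""Transfer of per-vertex fields between non-identical surface meshes.

A segmentation mesh and a hemodynamic-model mesh of the same chamber do
not share vertices, so fields must be projected: continuous fields by
closest-point projection onto the source surface with linear (barycentric)
finite-element interpolation, categorical labels by nearest source vertex
(interpolating a binary label is meaningless).  Target vertices farther
than a distance tolerance from the source surface — e.g. pulmonary-vein
extensions with no counterpart in the segmentation — keep their nearest
value but are counted as extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .fibrosis import FibrosisMask
from .mesh import SurfaceMesh

__all__ = ["TransferResult", "closest_point_transfer", "barycentric_transfer",
           "transfer_labels", "nearest_vertex_indices"]

DISTANCE_TOL_DEFAULT = 5.0  # mm; beyond this a target vertex counts as extrapolated


@dataclass
class TransferResult:
    """A transferred field plus projection diagnostics."""

    values: np.ndarray
    method: str
    distances: np.ndarray
    max_projection_distance: float
    n_extrapolated: int
    extrapolated: np.ndarray
    source_index: np.ndarray | None = None


def nearest_vertex_indices(source_vertices: np.ndarray,
                           target_points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Index of the nearest source vertex per target point, lowest index on ties."""
    source_vertices = np.asarray(source_vertices, float)
    target_points = np.asarray(target_points, float)
    if len(source_vertices) == 0:
        raise ValueError("source mesh has no vertices")
    tree = cKDTree(source_vertices)
    k = min(2, len(source_vertices))
    dist, idx = tree.query(target_points, k=k)
    if k == 1:
        return np.atleast_1d(idx), np.atleast_1d(dist)
    d1, i1 = dist[:, 0], idx[:, 0]
    # deterministic tie-break: among equidistant sources pick the lowest index
    tied = dist[:, 1] - d1 <= 1e-9 * (1.0 + d1)
    if np.any(tied):
        for j in np.nonzero(tied)[0]:
            cand = tree.query_ball_point(target_points[j],
                                         d1[j] * (1 + 1e-9) + 1e-12)
            if cand:
                i1[j] = min(cand)
    return i1, d1


def _as_field(source: SurfaceMesh, fld) -> np.ndarray:
    if isinstance(fld, str):
        fld = source.vertex_data[fld]
    fld = np.asarray(fld, dtype=np.float64)
    if fld.shape[0] != source.n_vertices:
        raise ValueError("field must be defined at every source vertex")
    return fld


def closest_point_transfer(source: SurfaceMesh, fld, target: SurfaceMesh,
                           distance_tol: float = DISTANCE_TOL_DEFAULT) -> TransferResult:
    """Each target vertex takes the value of the nearest source vertex."""
    values = _as_field(source, fld)
    idx, dist = nearest_vertex_indices(source.vertices, target.vertices)
    extrapolated = dist > distance_tol
    return TransferResult(values=values[idx], method="closest_point",
                          distances=dist,
                          max_projection_distance=float(dist.max(initial=0.0)),
                          n_extrapolated=int(extrapolated.sum()),
                          extrapolated=extrapolated, source_index=idx)


# ------------------------------------------------------- point-triangle

def _closest_on_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray,
                          c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closest point to ``p`` on each triangle ``(a, b, c)`` and its
    barycentric coordinates.  Vectorized version of the classic
    region-by-region projection; all inputs (k, 3)."""
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    k = len(p)
    bary = np.zeros((k, 3))
    done = np.zeros(k, dtype=bool)

    def settle(mask, u, v, w):
        m = mask & ~done
        bary[m, 0], bary[m, 1], bary[m, 2] = u[m], v[m], w[m]
        done[m] = True

    one = np.ones(k)
    zero = np.zeros(k)

    settle((d1 <= 0) & (d2 <= 0), one, zero, zero)                 # vertex a
    settle((d3 >= 0) & (d4 <= d3), zero, one, zero)                # vertex b
    settle((d6 >= 0) & (d5 <= d6), zero, zero, one)                # vertex c
    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), 1 - t_ab, t_ab, zero)  # edge ab
    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), 1 - t_ac, zero, t_ac)  # edge ac
    va = d3 * d6 - d5 * d4
    with np.errstate(divide="ignore", invalid="ignore"):
        t_bc = np.where((d4 - d3) + (d5 - d6) != 0,
                        (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
    settle((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
           zero, 1 - t_bc, t_bc)                                    # edge bc
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    settle(np.ones(k, dtype=bool), 1 - v - w, v, w)                 # interior

    closest = (bary[:, 0, None] * a + bary[:, 1, None] * b
               + bary[:, 2, None] * c)
    return closest, np.clip(bary, 0.0, 1.0)


def _project_to_surface(source: SurfaceMesh, points: np.ndarray,
                        k_candidates: int = 8):
    """Closest point on the source triangulation for each query point.

    Candidate triangles come from a centroid k-d tree; a ball query with
    the triangle circumradius bound then guarantees no nearer triangle
    was missed.  Ties go to the lowest triangle index.
    """
    if source.n_triangles == 0:
        raise ValueError("source mesh has no triangles")
    a, b, c = source.triangle_corners()
    centroids = (a + b + c) / 3.0
    r_max = float(np.sqrt(np.maximum.reduce([
        np.einsum("ij,ij->i", a - centroids, a - centroids),
        np.einsum("ij,ij->i", b - centroids, b - centroids),
        np.einsum("ij,ij->i", c - centroids, c - centroids)]).max()))
    tree = cKDTree(centroids)
    k = min(k_candidates, source.n_triangles)
    _, cand = tree.query(points, k=k)
    cand = np.atleast_2d(cand.reshape(len(points), -1))

    n = len(points)
    best_tri = np.zeros(n, dtype=np.int64)
    best_d2 = np.full(n, np.inf)
    best_bary = np.zeros((n, 3))
    best_pt = np.zeros((n, 3))

    def consider(rows, tris):
        cp, bary = _closest_on_triangles(points[rows], a[tris], b[tris], c[tris])
        d2 = np.einsum("ij,ij->i", points[rows] - cp, points[rows] - cp)
        # rows may repeat: keep only each row's best candidate (smallest
        # distance, then lowest triangle index) before comparing to the
        # running best
        order = np.lexsort((tris, d2, rows))
        first = np.ones(len(order), dtype=bool)
        first[1:] = rows[order][1:] != rows[order][:-1]
        keep = order[first]
        rr, dd, tt = rows[keep], d2[keep], tris[keep]
        better = (dd < best_d2[rr]) | ((dd == best_d2[rr]) & (tt < best_tri[rr]))
        rr = rr[better]
        best_d2[rr] = dd[better]
        best_tri[rr] = tt[better]
        best_bary[rr] = bary[keep][better]
        best_pt[rr] = cp[keep][better]

    rows = np.repeat(np.arange(n), cand.shape[1])
    consider(rows, cand.ravel())

    # exact pass: any triangle with a closer point has its centroid within
    # best distance + max centroid-to-corner radius
    radii = np.sqrt(best_d2) + r_max + 1e-12
    extra_rows, extra_tris = [], []
    seen = [set(row) for row in cand]
    balls = tree.query_ball_point(points, radii)
    for i, ball in enumerate(balls):
        for t in ball:
            if t not in seen[i]:
                extra_rows.append(i)
                extra_tris.append(t)
    if extra_rows:
        consider(np.array(extra_rows), np.array(extra_tris))

    return best_pt, np.sqrt(best_d2), best_tri, best_bary


def barycentric_transfer(source: SurfaceMesh, fld, target: SurfaceMesh,
                         distance_tol: float = DISTANCE_TOL_DEFAULT) -> TransferResult:
    """Project target vertices onto the source surface and interpolate
    the field with the linear finite-element (barycentric) weights of the
    containing triangle.  Exactly reproduces linear fields on planar
    patches and never leaves the source field's range."""
    values = _as_field(source, fld)
    _, dist, tri, bary = _project_to_surface(source, target.vertices)
    corner_vals = values[source.triangles[tri]]  # (n, 3) or (n, 3, d)
    if corner_vals.ndim == 2:
        out = np.einsum("ij,ij->i", bary, corner_vals)
    else:
        out = np.einsum("ij,ijk->ik", bary, corner_vals)
    extrapolated = dist > distance_tol
    return TransferResult(values=out, method="barycentric", distances=dist,
                          max_projection_distance=float(dist.max(initial=0.0)),
                          n_extrapolated=int(extrapolated.sum()),
                          extrapolated=extrapolated)


def transfer_labels(mask: FibrosisMask, source: SurfaceMesh,
                    target: SurfaceMesh,
                    distance_tol: float = DISTANCE_TOL_DEFAULT
                    ) -> tuple[FibrosisMask, TransferResult]:
    """Nearest-source-vertex transfer of the fibrotic/non-fibrotic label."""
    if mask.n_vertices != source.n_vertices:
        raise ValueError("mask length does not match source mesh")
    idx, dist = nearest_vertex_indices(source.vertices, target.vertices)
    extrapolated = dist > distance_tol
    out = FibrosisMask(fibrotic=mask.fibrotic[idx], threshold=mask.threshold,
                       included=mask.included[idx])
    result = TransferResult(values=out.fibrotic, method="closest_point",
                            distances=dist,
                            max_projection_distance=float(dist.max(initial=0.0)),
                            n_extrapolated=int(extrapolated.sum()),
                            extrapolated=extrapolated, source_index=idx)
    return out, result
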