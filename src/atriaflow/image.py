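"""LGE-like intensity volumes and wall-normal intensity projection.

The wall intensity at a surface vertex is the maximum voxel intensity
sampled along the inward-facing normal, emulating how late-gadolinium
enhancement is projected "through the wall" onto an epicardial surface.
Volumes are axis-aligned scalar grids with anisotropic spacing (the
clinical default here is 1.25 x 1.25 x 2.5 mm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .mesh import SurfaceMesh

log = logging.getLogger(__name__)

__all__ = ["IntensityVolume", "read_nifti", "write_nifti",
           "sample_nearest", "project_image_to_surface"]


@dataclass
class IntensityVolume:
    """Axis-aligned scalar intensity grid.

    ``data[i, j, k]`` is the intensity of the voxel whose center sits at
    ``origin + (i, j, k) * spacing`` (mm).  Intensities are arbitrary
    units; only their ratio to the blood-pool mean matters downstream.
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.array([1.25, 1.25, 2.5]))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive on all axes")


def read_nifti(path) -> IntensityVolume:
    """Load an axis-aligned NIfTI volume (spacing from zooms, origin from affine)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    spacing = np.abs(np.asarray(img.header.get_zooms()[:3], dtype=np.float64))
    origin = np.asarray(img.affine[:3, 3], dtype=np.float64)
    return IntensityVolume(data, spacing=spacing, origin=origin)


def write_nifti(volume: IntensityVolume, path) -> None:
    affine = np.diag([*volume.spacing, 1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(volume.data, affine), str(path))


def voxel_index(volume: IntensityVolume, points: np.ndarray) -> np.ndarray:
    """Nearest-voxel index of each point; may fall outside the grid."""
    return np.rint((np.asarray(points, float) - volume.origin)
                   / volume.spacing).astype(np.int64)


def sample_nearest(volume: IntensityVolume, points: np.ndarray) -> np.ndarray:
    """Nearest-voxel lookup; NaN for points outside the grid."""
    idx = voxel_index(volume, points)
    shape = np.array(volume.data.shape)
    inside = np.all((idx >= 0) & (idx < shape), axis=-1)
    out = np.full(idx.shape[:-1], np.nan)
    ii = idx[inside]
    out[inside] = volume.data[ii[:, 0], ii[:, 1], ii[:, 2]]
    return out


def project_image_to_surface(volume: IntensityVolume, mesh: SurfaceMesh,
                             normals: np.ndarray, depth: float = 2.5,
                             step: float | None = None) -> np.ndarray:
    """Maximum intensity along each vertex's inward normal.

    Samples the volume (nearest voxel) at ``vertex + t * normal`` for
    ``t in {0, step, ..., depth}`` and returns the per-vertex maximum.
    ``step`` defaults to half the smallest voxel spacing so no traversed
    voxel is skipped.  Vertices whose samples all fall outside the volume
    get NaN; a warning is logged when more than 10% are missing.
    """
    if depth <= 0:
        raise ValueError("projection depth must be positive")
    if step is None:
        step = float(volume.spacing.min()) / 2.0
    if step <= 0:
        raise ValueError("projection step must be positive")
    normals = np.asarray(normals, dtype=np.float64)
    if normals.shape != mesh.vertices.shape:
        raise ValueError("normals must be one unit 3-vector per vertex")
    ts = np.arange(0.0, depth + 0.5 * step, step)
    ts[-1] = min(ts[-1], depth)
    # (n_vertices, n_samples, 3)
    positions = mesh.vertices[:, None, :] + ts[None, :, None] * normals[:, None, :]
    samples = sample_nearest(volume, positions)
    all_nan = np.all(np.isnan(samples), axis=1)
    intensity = np.full(mesh.n_vertices, np.nan)
    if not all_nan.all():
        intensity[~all_nan] = np.nanmax(samples[~all_nan], axis=1)
    n_missing = int(all_nan.sum())
    if n_missing:
        frac = n_missing / mesh.n_vertices
        msg = ("%d/%d vertices (%.1f%%) had no in-bounds sample along the "
               "projection ray")
        if frac > 0.10:
            log.warning(msg, n_missing, mesh.n_vertices, 100 * frac)
        else:
            log.info(msg, n_missing, mesh.n_vertices, 100 * frac)
    return intensity
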