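"""Synthetic chamber meshes, fibrosis patterns, intensity volumes and
pulsatile wall-shear series with known ground truth.

The generator stands in for patient LGE-MRI and cluster-scale CFD so the
whole pipeline is exercisable at desk scale.  It emulates the study
conditions this pipeline targets: an atrium-sized ellipsoidal chamber
wall (tens of thousands of surface points at clinical scale; 5,000 by
default here), interdigitated fibrotic patches at burdens in the 6-25%
range, LGE-like intensity volumes at 1.25 x 1.25 x 2.5 mm voxel spacing
with fibrotic wall brighter than the blood pool, and pulsatile wall
shear over a 0.92 s cycle in 92 frames where fibrotic wall sees lower
shear magnitude and more direction reversal.  Fibrotic hemodynamic
effects are injected directly into the shear field — the object under
test is the metric and statistics pipeline, not a flow solver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, cKDTree

from .fibrosis import FibrosisMask
from .image import IntensityVolume
from .mesh import SurfaceMesh, compute_area_weights, vertex_normals
from .metrics import (CYCLE_LENGTH_DEFAULT, N_FRAMES_DEFAULT, WSSVectorSeries,
                      uniform_times)

log = logging.getLogger(__name__)

__all__ = ["SyntheticCaseSpec", "GroundTruth", "SyntheticCase",
           "make_chamber_mesh", "seed_fibrotic_patches",
           "synth_intensity_volume", "synth_wss_series",
           "analytic_sinusoid_oracle", "generate_case", "pulsatile_waveform"]

# harmonic mix (order, amplitude, phase) of the pulsatile waveform; the
# baseline of 1 keeps it positive (min ~0.15) so healthy wall shear never
# reverses on its own
HARMONICS_DEFAULT = ((1, 0.6, 0.0), (2, 0.25, 0.8))


@dataclass
class SyntheticCaseSpec:
    """Everything needed to generate one synthetic case.

    Defaults are the desk-scale study conditions: a 45 x 35 x 25 mm
    semi-axis ellipsoid (~165 ml, the scale of a dilated atrium), 5,000
    wall points, 15% fibrotic burden in 3 patches, base wall shear
    amplitude 0.8 Pa with fibrotic magnitude factor 0.7 and a reversal
    fraction of 0.25 of the cycle, blood-pool intensity 100 with 1.5x
    fibrotic contrast and 2% intensity noise.
    """

    seed: int = 0
    n_vertices: int = 5000
    semi_axes: tuple = (45.0, 35.0, 25.0)        # mm
    bump_height: float = 0.0                     # mm; >0 adds an appendage-like bulge
    bump_direction: tuple = (1.0, 0.0, 0.0)
    bump_width: float = 0.5                      # rad, angular Gaussian width
    target_fibrotic_burden: float = 15.0         # percent of wall area
    n_patches: int = 3
    base_amplitude: float = 0.8                  # Pa
    harmonics: tuple = HARMONICS_DEFAULT
    magnitude_factor: float = 0.7                # fibrotic shear magnitude multiplier
    reversal_fraction: float = 0.25              # fraction of cycle reversed in fibrosis
    noise_sd: float = 0.04                       # Pa, per frame/component
    n_frames: int = N_FRAMES_DEFAULT
    cycle_length: float = CYCLE_LENGTH_DEFAULT   # s
    blood_pool_mean: float = 100.0               # intensity units
    contrast: float = 1.5                        # fibrotic wall / blood pool
    intensity_noise_sd: float = 2.0              # intensity units
    voxel_spacing: tuple = (1.25, 1.25, 2.5)     # mm
    wall_depth: float = 2.5                      # mm, stamped/projected wall thickness

    def __post_init__(self) -> None:
        if not 0 <= self.target_fibrotic_burden <= 100:
            raise ValueError("target burden must be in [0, 100]")
        if not 0 <= self.reversal_fraction <= 0.5:
            raise ValueError("reversal fraction must be in [0, 0.5]")
        if not 0 < self.magnitude_factor <= 1:
            raise ValueError("magnitude factor must be in (0, 1]")


@dataclass
class GroundTruth:
    """Generator-side truth for recovery tests."""

    mask: FibrosisMask
    expected_tawss: dict            # region -> Pa (noise-free)
    expected_osi: dict              # region -> dimensionless (noise-free)
    params: dict = field(default_factory=dict)


@dataclass
class SyntheticCase:
    spec: SyntheticCaseSpec
    mesh: SurfaceMesh
    mask: FibrosisMask
    achieved_burden: float
    volume: IntensityVolume
    series: WSSVectorSeries
    truth: GroundTruth


# ----------------------------------------------------------------- mesh

def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    theta = 2.0 * np.pi * i / golden
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def make_chamber_mesh(n_vertices: int = 5000,
                      semi_axes=(45.0, 35.0, 25.0),
                      bump_height: float = 0.0,
                      bump_direction=(1.0, 0.0, 0.0),
                      bump_width: float = 0.5,
                      seed: int = 0) -> SurfaceMesh:
    """Watertight ellipsoidal chamber wall with an exact vertex count.

    A Fibonacci lattice on the ellipsoid is triangulated by its convex
    hull, which hits any requested vertex count exactly (icosphere
    subdivision would quantize counts to 642/2562/10242/...).  The
    lattice is given a small seeded rotation so different seeds give
    different but statistically identical meshes.  An optional smooth
    radial bulge emulates an appendage; it is applied after hulling so
    the triangulation stays valid.
    """
    if n_vertices < 12:
        raise ValueError("need at least 12 vertices for a chamber mesh")
    rng = np.random.default_rng(seed)
    dirs = _fibonacci_directions(n_vertices)
    # seeded random rotation (QR of a Gaussian matrix)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    dirs = dirs @ q.T
    pts = dirs * np.asarray(semi_axes, float)

    hull = ConvexHull(pts)
    if len(hull.vertices) != n_vertices:   # strictly convex: should not happen
        log.warning("convex hull dropped %d lattice point(s)",
                    n_vertices - len(hull.vertices))
        remap = -np.ones(n_vertices, dtype=np.int64)
        remap[hull.vertices] = np.arange(len(hull.vertices))
        pts = pts[hull.vertices]
        tris = remap[hull.simplices]
    else:
        tris = hull.simplices.astype(np.int64)

    # orient all triangles outward
    a, b, c = pts[tris[:, 0]], pts[tris[:, 1]], pts[tris[:, 2]]
    outward = np.einsum("ij,ij->i", np.cross(b - a, c - a),
                        (a + b + c) / 3.0 - pts.mean(axis=0))
    flip = outward < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]

    if bump_height > 0:
        d = np.asarray(bump_direction, float)
        d = d / np.linalg.norm(d)
        radial = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        ang = np.arccos(np.clip(radial @ d, -1.0, 1.0))
        pts = pts + (bump_height * np.exp(-(ang / bump_width) ** 2))[:, None] * radial

    return SurfaceMesh(pts, tris)


# ----------------------------------------------------------------- fibrosis

def seed_fibrotic_patches(mesh: SurfaceMesh, target_burden: float,
                          n_patches: int = 3, seed: int = 0,
                          tolerance_pp: float = 1.0) -> tuple[FibrosisMask, float]:
    """Grow patches around seeded centers to a target area burden.

    All patches grow together as Euclidean balls around their centers
    (on a convex chamber that is geodesic-ball-like): vertices are
    labelled fibrotic in order of distance to the nearest center until
    the area-weighted burden is as close as possible to the target.
    Deterministic per seed.  Returns the mask and the achieved burden;
    warns if the achieved burden misses the target by more than
    ``tolerance_pp`` percentage points.
    """
    if not 0 <= target_burden <= 100:
        raise ValueError("target burden must be in [0, 100]")
    if n_patches < 1:
        raise ValueError("need at least one patch")
    mask = np.zeros(mesh.n_vertices, dtype=bool)
    if target_burden == 0:
        return FibrosisMask(fibrotic=mask), 0.0
    rng = np.random.default_rng(seed)
    centers = rng.choice(mesh.n_vertices, size=min(n_patches, mesh.n_vertices),
                         replace=False)
    dist = cKDTree(mesh.vertices[centers]).query(mesh.vertices)[0]
    order = np.argsort(dist, kind="stable")
    areas = compute_area_weights(mesh).per_vertex_area
    total = areas.sum()
    cum = 100.0 * np.cumsum(areas[order]) / total
    k = int(np.argmin(np.abs(cum - target_burden))) + 1
    mask[order[:k]] = True
    achieved = float(cum[k - 1])
    if abs(achieved - target_burden) > tolerance_pp:
        log.warning("achieved burden %.2f%% misses target %.2f%% by more "
                    "than %.1f pp", achieved, target_burden, tolerance_pp)
    return FibrosisMask(fibrotic=mask), achieved


# ----------------------------------------------------------------- image

def synth_intensity_volume(mesh: SurfaceMesh, mask: FibrosisMask,
                           blood_pool_mean: float = 100.0,
                           contrast: float = 1.5,
                           noise_sd: float = 0.0,
                           spacing=(1.25, 1.25, 2.5),
                           wall_depth: float = 2.5,
                           seed: int = 0) -> IntensityVolume:
    """LGE-like intensity volume consistent with a fibrosis mask.

    The grid is filled with the blood-pool mean; voxels traversed by
    each vertex's inward wall ray (depth ``wall_depth``) are stamped with
    blood_pool_mean x contrast for fibrotic vertices and blood_pool_mean
    for non-fibrotic ones.  Where rays of both classes share a voxel the
    vertex nearest the voxel center wins, keeping the class boundary
    sharp.  Gaussian noise is added last.  With zero noise the forward
    projection + IIR pipeline recovers the mask up to voxelization error
    at patch boundaries.
    """
    if mask.n_vertices != mesh.n_vertices:
        raise ValueError("mask length does not match mesh")
    spacing = np.asarray(spacing, float)
    margin = wall_depth + 2.0 * spacing.max()
    lo = mesh.vertices.min(axis=0) - margin
    hi = mesh.vertices.max(axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    data = np.full(shape, float(blood_pool_mean))
    vol = IntensityVolume(data, spacing=spacing, origin=lo)

    normals = vertex_normals(mesh, orientation="inward")
    step = float(spacing.min()) / 2.0
    ts = np.arange(0.0, wall_depth + 0.5 * step, step)
    pos = mesh.vertices[:, None, :] + ts[None, :, None] * normals[:, None, :]
    pos = pos.reshape(-1, 3)
    vidx = np.rint((pos - vol.origin) / spacing).astype(np.int64)
    inside = np.all((vidx >= 0) & (vidx < shape), axis=1)

    owner = np.repeat(np.arange(mesh.n_vertices), len(ts))[inside]
    vidx = vidx[inside]
    centers = vol.origin + vidx * spacing
    d2 = np.einsum("ij,ij->i", centers - mesh.vertices[owner],
                   centers - mesh.vertices[owner])
    # assign farthest first so the nearest stamping vertex wins each voxel
    order = np.argsort(-d2, kind="stable")
    flat = np.ravel_multi_index(tuple(vidx[order].T), tuple(shape))
    values = np.where(mask.fibrotic[owner[order]],
                      blood_pool_mean * contrast, float(blood_pool_mean))
    data.ravel()[flat] = values

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data += rng.normal(0.0, noise_sd, size=data.shape)
    return vol


# ----------------------------------------------------------------- WSS

def pulsatile_waveform(times: np.ndarray, cycle_length: float,
                       harmonics=HARMONICS_DEFAULT) -> np.ndarray:
    """Positive-biased harmonic mix: 1 + sum(amp * sin(2*pi*k*t/T + phase))."""
    w = np.ones_like(times)
    for order, amp, phase in harmonics:
        w = w + amp * np.sin(2.0 * np.pi * order * times / cycle_length + phase)
    return w


def _tangent_directions(mesh: SurfaceMesh) -> np.ndarray:
    """Deterministic unit tangents from the azimuthal direction of each
    vertex about the chamber centroid (degenerate only exactly on the
    polar axis, which the lattice avoids)."""
    rel = mesh.vertices - mesh.centroid
    phi = np.arctan2(rel[:, 1], rel[:, 0])
    return np.column_stack([-np.sin(phi), np.cos(phi), np.zeros_like(phi)])


def _waveform_stats(w: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Time mean of |w| and of w under the periodic quadrature weights."""
    total = weights.sum()
    return float((weights * np.abs(w)).sum() / total), \
        float((weights * w).sum() / total)


def synth_wss_series(mesh: SurfaceMesh, mask: FibrosisMask,
                     base_amplitude: float = 0.8,
                     harmonics=HARMONICS_DEFAULT,
                     magnitude_factor: float = 0.7,
                     reversal_fraction: float = 0.25,
                     noise_sd: float = 0.04,
                     n_frames: int = N_FRAMES_DEFAULT,
                     cycle_length: float = CYCLE_LENGTH_DEFAULT,
                     seed: int = 0) -> tuple[WSSVectorSeries, GroundTruth]:
    """Pulsatile WSS vectors with injected fibrotic effects.

    Every vertex carries tau(t) = A * w(t) * e along its deterministic
    tangent e, with w the positive pulsatile waveform.  Fibrotic vertices
    get A scaled by ``magnitude_factor`` (lower shear) and the waveform
    shifted down by its ``reversal_fraction`` quantile, so that fraction
    of the cycle reverses direction (higher OSI).  Isotropic Gaussian
    noise is added per frame and component.  The returned ground truth
    records the noise-free per-region TAWSS and OSI.
    """
    if not 0 <= reversal_fraction <= 0.5:
        raise ValueError("reversal fraction must be in [0, 0.5]")
    if mask.n_vertices != mesh.n_vertices:
        raise ValueError("mask length does not match mesh")
    rng = np.random.default_rng(seed)
    times = uniform_times(n_frames, cycle_length)
    w = pulsatile_waveform(times, cycle_length, harmonics)
    shift = float(np.quantile(w, reversal_fraction)) if reversal_fraction > 0 else 0.0
    w_fib = magnitude_factor * (w - shift)

    tangents = _tangent_directions(mesh)
    amp_t = np.where(mask.fibrotic[None, :], w_fib[:, None], w[:, None])
    tau = base_amplitude * amp_t[:, :, None] * tangents[None, :, :]
    if noise_sd > 0:
        tau = tau + rng.normal(0.0, noise_sd, size=tau.shape)
    series = WSSVectorSeries(tau=tau, times=times, cycle_length=cycle_length)

    qw = series.quadrature_weights()
    mag_non, mean_non = _waveform_stats(base_amplitude * w, qw)
    mag_fib, mean_fib = _waveform_stats(base_amplitude * w_fib, qw)
    truth = GroundTruth(
        mask=mask,
        expected_tawss={"non_fibrotic": mag_non, "fibrotic": mag_fib},
        expected_osi={
            "non_fibrotic": 0.5 * (1 - abs(mean_non) / mag_non) if mag_non else 0.0,
            "fibrotic": 0.5 * (1 - abs(mean_fib) / mag_fib) if mag_fib else 0.0},
        params={"base_amplitude": base_amplitude,
                "magnitude_factor": magnitude_factor,
                "reversal_fraction": reversal_fraction,
                "noise_sd": noise_sd, "seed": seed})
    return series, truth


# ----------------------------------------------------------------- oracle

def analytic_sinusoid_oracle(amplitude: float, offset: float,
                             cycle_length: float = CYCLE_LENGTH_DEFAULT
                             ) -> tuple[float, float]:
    """Closed-form TAWSS and OSI for tau(t) = (offset + A sin(2*pi*t/T)) e.

    The continuous-time values, for checking the quadrature:
    mean |c + A sin| over a period is |c| when |c| >= A and otherwise
    (2/pi) * (|c| * asin(|c|/A) + A * cos(asin(|c|/A))); the time-mean
    vector magnitude is |c|, so OSI = 0.5 * (1 - |c| / TAWSS).
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    a, c = float(amplitude), abs(float(offset))
    if a == 0 and c == 0:
        return 0.0, 0.0
    if c >= a:
        tawss = c
    else:
        alpha = np.arcsin(c / a)
        tawss = (2.0 / np.pi) * (c * alpha + a * np.cos(alpha))
    osi = 0.5 * (1.0 - c / tawss) if tawss > 0 else 0.0
    return float(tawss), float(osi)


# ----------------------------------------------------------------- case

def generate_case(spec: SyntheticCaseSpec) -> SyntheticCase:
    """Generate a full synthetic case (mesh, mask, volume, WSS series).

    Sub-stages derive independent seeds from ``spec.seed`` so a case is
    reproducible end to end.
    """
    s_mesh, s_patch, s_vol, s_wss = np.random.SeedSequence(spec.seed).generate_state(4)
    mesh = make_chamber_mesh(spec.n_vertices, spec.semi_axes,
                             bump_height=spec.bump_height,
                             bump_direction=spec.bump_direction,
                             bump_width=spec.bump_width, seed=int(s_mesh))
    mask, achieved = seed_fibrotic_patches(mesh, spec.target_fibrotic_burden,
                                           spec.n_patches, seed=int(s_patch))
    volume = synth_intensity_volume(mesh, mask,
                                    blood_pool_mean=spec.blood_pool_mean,
                                    contrast=spec.contrast,
                                    noise_sd=spec.intensity_noise_sd,
                                    spacing=spec.voxel_spacing,
                                    wall_depth=spec.wall_depth, seed=int(s_vol))
    series, truth = synth_wss_series(mesh, mask,
                                     base_amplitude=spec.base_amplitude,
                                     harmonics=spec.harmonics,
                                     magnitude_factor=spec.magnitude_factor,
                                     reversal_fraction=spec.reversal_fraction,
                                     noise_sd=spec.noise_sd,
                                     n_frames=spec.n_frames,
                                     cycle_length=spec.cycle_length,
                                     seed=int(s_wss))
    return SyntheticCase(spec=spec, mesh=mesh, mask=mask,
                         achieved_burden=achieved, volume=volume,
                         series=series, truth=truth)
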