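"""Image-intensity-ratio fibrosis classification and burden quantification.

Wall intensities are normalized by the mean blood-pool intensity to the
dimensionless image intensity ratio (IIR); vertices whose IIR exceeds a
fixed threshold (1.22 by default, the standard LGE-MRI cutoff for atrial
fibrosis) are classified fibrotic.  Fibrotic burden is the fibrotic
fraction of the wall, area-weighted by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .mesh import SurfaceMesh, compute_area_weights

log = logging.getLogger(__name__)

__all__ = ["IIRField", "FibrosisMask", "compute_iir", "classify_fibrosis",
           "fibrotic_burden_percent", "IIR_THRESHOLD_DEFAULT"]

IIR_THRESHOLD_DEFAULT = 1.22


@dataclass
class IIRField:
    """Per-vertex image intensity ratio and the blood-pool mean it used."""

    iir: np.ndarray
    blood_pool_mean: float

    def __post_init__(self) -> None:
        self.iir = np.asarray(self.iir, dtype=np.float64)


@dataclass
class FibrosisMask:
    """Boolean fibrotic label per vertex.

    ``included`` marks vertices that carried a valid intensity; excluded
    vertices belong to neither region and drop out of burden and region
    statistics.  Included vertices partition exactly into fibrotic and
    non-fibrotic.
    """

    fibrotic: np.ndarray
    threshold: float = IIR_THRESHOLD_DEFAULT
    included: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fibrotic = np.asarray(self.fibrotic, dtype=bool)
        if self.included is None:
            self.included = np.ones_like(self.fibrotic)
        else:
            self.included = np.asarray(self.included, dtype=bool)
        if self.included.shape != self.fibrotic.shape:
            raise ValueError("included mask must match fibrotic mask length")
        # excluded vertices are never fibrotic
        self.fibrotic = self.fibrotic & self.included

    @property
    def n_vertices(self) -> int:
        return len(self.fibrotic)

    @property
    def n_excluded(self) -> int:
        return int((~self.included).sum())

    @property
    def non_fibrotic(self) -> np.ndarray:
        return self.included & ~self.fibrotic


def compute_iir(intensity: np.ndarray, blood_pool_mean: float) -> IIRField:
    """intensity / blood_pool_mean; NaN intensities stay NaN."""
    if not blood_pool_mean > 0:
        raise ValueError("blood_pool_mean must be positive")
    intensity = np.asarray(intensity, dtype=np.float64)
    return IIRField(iir=intensity / float(blood_pool_mean),
                    blood_pool_mean=float(blood_pool_mean))


def classify_fibrosis(iir: IIRField | np.ndarray,
                      threshold: float = IIR_THRESHOLD_DEFAULT) -> FibrosisMask:
    """Fibrotic where IIR is strictly above the threshold.

    The cutoff is strict ("more than" the threshold): IIR exactly equal
    to the threshold is non-fibrotic.  Vertices with missing (NaN) IIR
    are excluded from both regions; the count is logged.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    values = iir.iir if isinstance(iir, IIRField) else np.asarray(iir, float)
    included = np.isfinite(values)
    n_missing = int((~included).sum())
    if n_missing:
        log.info("%d vertex/vertices with missing IIR excluded from "
                 "classification", n_missing)
    with np.errstate(invalid="ignore"):
        fibrotic = included & (values > threshold)
    return FibrosisMask(fibrotic=fibrotic, threshold=float(threshold),
                        included=included)


def fibrotic_burden_percent(mesh: SurfaceMesh, mask: FibrosisMask,
                            weighting: str = "area") -> float:
    """Fibrotic percentage of the wall, in [0, 100].

    ``area`` (default) weighs vertices by their incident-triangle area;
    ``count`` uses the plain vertex fraction.  Excluded vertices drop
    out of both numerator and denominator.
    """
    if mesh.n_vertices == 0:
        raise ValueError("mesh has no vertices")
    if mask.n_vertices != mesh.n_vertices:
        raise ValueError("mask length does not match mesh")
    if weighting == "area":
        w = compute_area_weights(mesh).per_vertex_area
    elif weighting == "count":
        w = np.ones(mesh.n_vertices)
    else:
        raise ValueError("weighting must be 'area' or 'count'")
    total = float(w[mask.included].sum())
    if total <= 0:
        raise ValueError("no included vertices with positive weight")
    return 100.0 * float(w[mask.fibrotic].sum()) / total
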