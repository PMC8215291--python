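"""Wall-shear-derived hemodynamic metrics over one cardiac cycle.

Given the wall shear stress vector tau(t) at each surface point over a
single cycle of length T (0.92 s at 92 frames by default), the four
standard metrics are

    TAWSS = (1/T) * integral ||tau|| dt          (Pa)
    OSI   = 0.5 * (1 - ||integral tau dt|| / integral ||tau|| dt)
    ECAP  = OSI / TAWSS                          (1/Pa)
    RRT   = 1 / ((1 - 2*OSI) * TAWSS)
          = 1 / ||(1/T) integral tau dt||        (1/Pa)

OSI lies in [0, 0.5] (Cauchy-Schwarz); 0.5 means full direction reversal.
ECAP amplifies slow oscillating near-wall flow (low TAWSS, high OSI) and
RRT is a residence-time proxy.  Integrals use the trapezoidal rule with
periodic closure: the series represents one full cycle, so the segment
from the last frame back to the first is included.

For cross-case comparison TAWSS, ECAP and RRT are normalized by their
mean over the wall (model mean 1); OSI, already bounded and
dimensionless, is never normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WSSVectorSeries", "HemodynamicMetrics", "time_average_wss",
           "oscillatory_shear_index", "ecap", "rrt", "normalize_by_mean",
           "compute_metrics", "uniform_times", "n_frames_for_cycle",
           "CYCLE_LENGTH_DEFAULT", "N_FRAMES_DEFAULT", "RRT_CAP_DEFAULT"]

CYCLE_LENGTH_DEFAULT = 0.92   # s, one cardiac cycle in sinus rhythm
N_FRAMES_DEFAULT = 92         # frames per cycle (0.01 s output resolution)
RRT_CAP_DEFAULT = 1e9         # 1/Pa, stands in for infinite residence time


def n_frames_for_cycle(cycle_length: float = CYCLE_LENGTH_DEFAULT,
                       dt: float = 0.01) -> int:
    """Number of uniformly spaced output frames covering one cycle."""
    if cycle_length <= 0 or dt <= 0:
        raise ValueError("cycle_length and dt must be positive")
    n = round(cycle_length / dt)
    if not np.isclose(n * dt, cycle_length, rtol=1e-9):
        raise ValueError(f"cycle length {cycle_length} is not a multiple of dt {dt}")
    return int(n)


def uniform_times(n_frames: int = N_FRAMES_DEFAULT,
                  cycle_length: float = CYCLE_LENGTH_DEFAULT) -> np.ndarray:
    """Frame timestamps 0, T/n, ..., T*(n-1)/n for a periodic cycle."""
    return np.arange(n_frames) * (cycle_length / n_frames)


@dataclass
class WSSVectorSeries:
    """Wall shear stress vectors (Pa): ``tau[frame, point, :]`` over one cycle."""

    tau: np.ndarray
    times: np.ndarray | None = None
    cycle_length: float = CYCLE_LENGTH_DEFAULT

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=np.float64)
        if self.tau.ndim != 3 or self.tau.shape[2] != 3:
            raise ValueError("tau must have shape (n_frames, n_points, 3)")
        if self.n_frames < 2:
            raise ValueError("a series needs at least 2 frames")
        if self.times is None:
            self.times = uniform_times(self.n_frames, self.cycle_length)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.times.shape != (self.n_frames,):
            raise ValueError("times must have one entry per frame")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times[0] < 0 or self.times[-1] >= self.cycle_length:
            raise ValueError("times must lie within [0, cycle_length)")
        if not np.all(np.isfinite(self.tau)):
            fr, pt = np.argwhere(~np.isfinite(self.tau).all(axis=2))[0]
            raise ValueError(f"non-finite WSS vector at frame {fr}, point {pt}")

    @property
    def n_frames(self) -> int:
        return self.tau.shape[0]

    @property
    def n_points(self) -> int:
        return self.tau.shape[1]

    def quadrature_weights(self) -> np.ndarray:
        """Trapezoidal weights with periodic closure; they sum to T."""
        t = self.times
        t_ext = np.concatenate([[t[-1] - self.cycle_length], t,
                                [t[0] + self.cycle_length]])
        return 0.5 * (t_ext[2:] - t_ext[:-2])


def _integrals(series: WSSVectorSeries) -> tuple[np.ndarray, np.ndarray]:
    """(integral ||tau|| dt, integral tau dt) per point."""
    w = series.quadrature_weights()
    mag = np.linalg.norm(series.tau, axis=2)
    int_mag = np.einsum("f,fp->p", w, mag)
    int_vec = np.einsum("f,fpc->pc", w, series.tau)
    return int_mag, int_vec


def time_average_wss(series: WSSVectorSeries) -> np.ndarray:
    """Cycle-averaged WSS magnitude per point (Pa)."""
    int_mag, _ = _integrals(series)
    return int_mag / series.cycle_length


def oscillatory_shear_index(series: WSSVectorSeries) -> np.ndarray:
    """OSI per point; 0 by convention where the shear vanishes all cycle."""
    int_mag, int_vec = _integrals(series)
    out = np.zeros(series.n_points)
    ok = int_mag > 0
    out[ok] = 0.5 * (1.0 - np.linalg.norm(int_vec[ok], axis=1) / int_mag[ok])
    # quadrature round-off can leave tiny negatives / >0.5 excursions
    return np.clip(out, 0.0, 0.5)


def ecap(tawss: np.ndarray, osi: np.ndarray) -> np.ndarray:
    """OSI / TAWSS (1/Pa); NaN (undefined, excluded from means) where TAWSS = 0."""
    tawss = np.asarray(tawss, float)
    osi = np.asarray(osi, float)
    if tawss.shape != osi.shape:
        raise ValueError("tawss and osi must have the same shape")
    out = np.full_like(tawss, np.nan)
    ok = tawss > 0
    out[ok] = osi[ok] / tawss[ok]
    return out


def rrt(tawss: np.ndarray, osi: np.ndarray, cap: float = RRT_CAP_DEFAULT,
        eps: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """1 / ((1 - 2*OSI) * TAWSS) per point, with a cap.

    Equals the reciprocal magnitude of the time-mean WSS vector.  Where
    the denominator falls below ``eps`` (pure reversal or zero shear,
    i.e. infinite residence time) the value is capped at ``cap`` and the
    returned boolean mask flags it.
    """
    tawss = np.asarray(tawss, float)
    osi = np.asarray(osi, float)
    if tawss.shape != osi.shape:
        raise ValueError("tawss and osi must have the same shape")
    denom = (1.0 - 2.0 * osi) * tawss
    capped = denom <= eps
    out = np.full_like(tawss, cap)
    out[~capped] = 1.0 / denom[~capped]
    out = np.minimum(out, cap)
    return out, capped


def normalize_by_mean(values: np.ndarray, include: np.ndarray | None = None,
                      weights: np.ndarray | None = None) -> np.ndarray:
    """Divide a field by its (optionally weighted) mean over included points.

    The result has mean 1 over the included points; scaling the input by
    any k > 0 leaves it unchanged.  NaN entries are always excluded from
    the mean and stay NaN.
    """
    values = np.asarray(values, dtype=np.float64)
    ok = np.isfinite(values)
    if include is not None:
        ok = ok & np.asarray(include, bool)
    if weights is None:
        w = np.ones_like(values)
    else:
        w = np.asarray(weights, float)
    wsum = float(w[ok].sum())
    if not wsum > 0:
        raise ValueError("no included points with positive weight")
    mean = float((w[ok] * values[ok]).sum()) / wsum
    if not mean > 0:
        raise ValueError("field mean must be positive for normalization")
    return values / mean


@dataclass
class HemodynamicMetrics:
    """Per-point TAWSS/OSI/ECAP/RRT, raw and (for TAWSS/ECAP/RRT) normalized."""

    tawss: np.ndarray
    osi: np.ndarray
    ecap: np.ndarray
    rrt: np.ndarray
    tawss_norm: np.ndarray | None = None
    ecap_norm: np.ndarray | None = None
    rrt_norm: np.ndarray | None = None
    n_ecap_undefined: int = 0
    n_rrt_capped: int = 0
    rrt_capped: np.ndarray = field(default=None, repr=False)

    RAW = ("tawss", "osi", "ecap", "rrt")

    def raw_fields(self) -> dict:
        return {name: getattr(self, name) for name in self.RAW}

    def comparison_fields(self) -> dict:
        """Fields used for cross-case comparison: normalized TAWSS/ECAP/RRT
        (when available) and raw OSI."""
        return {"tawss": self.tawss if self.tawss_norm is None else self.tawss_norm,
                "osi": self.osi,
                "ecap": self.ecap if self.ecap_norm is None else self.ecap_norm,
                "rrt": self.rrt if self.rrt_norm is None else self.rrt_norm}


def compute_metrics(series: WSSVectorSeries, normalize: bool = True,
                    weights: np.ndarray | None = None,
                    include: np.ndarray | None = None,
                    rrt_cap: float = RRT_CAP_DEFAULT) -> HemodynamicMetrics:
    """All four metrics from one WSS series, plus normalized variants.

    ``weights`` (e.g. per-vertex areas) and ``include`` control which
    points define the normalization means.  Capped RRT values are
    excluded from the RRT normalization mean.
    """
    tawss = time_average_wss(series)
    osi = oscillatory_shear_index(series)
    e = ecap(tawss, osi)
    r, capped = rrt(tawss, osi, cap=rrt_cap)
    m = HemodynamicMetrics(tawss=tawss, osi=osi, ecap=e, rrt=r,
                           n_ecap_undefined=int(np.isnan(e).sum()),
                           n_rrt_capped=int(capped.sum()),
                           rrt_capped=capped)
    if normalize:
        inc = np.ones(series.n_points, bool) if include is None \
            else np.asarray(include, bool)
        m.tawss_norm = normalize_by_mean(tawss, inc, weights)
        m.ecap_norm = normalize_by_mean(e, inc, weights)
        m.rrt_norm = normalize_by_mean(r, inc & ~capped, weights)
    return m
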