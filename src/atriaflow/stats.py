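"""Aberrant-burden quantification and fibrotic vs non-fibrotic statistics.

Per case: the wall is split into fibrotic and non-fibrotic regions and
each hemodynamic metric is compared between them.  Normality is checked
per region with a one-sample Kolmogorov-Smirnov test on z-scored values;
if either region departs from normality the regions are compared with a
two-sided Mann-Whitney U test, otherwise with Welch's t-test.  At
clinical point counts (tens of thousands of wall points) normality
essentially always rejects, so the rank test is the practical default.
Descriptives are mean +/- standard error throughout; significance is
p < 0.05.  No multiple-testing correction is applied across the four
metrics.

Across cases: per-metric region means are averaged over cases (normalized
values for TAWSS/ECAP/RRT, raw OSI), compared with a paired test chosen
by the same normality rule, and the aberrant hemodynamic burden is
regressed on fibrotic burden by ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as sps

from .fibrosis import FibrosisMask
from .mesh import SurfaceMesh, compute_area_weights

__all__ = ["GroupStats", "MetricComparison", "RegionComparison", "CaseReport",
           "CohortReport", "aberrant_burden", "region_compare",
           "compare_regions", "cohort_summary", "linear_fit_r2", "mean_se"]

ALPHA_DEFAULT = 0.05
METRICS = ("tawss", "osi", "ecap", "rrt")


def mean_se(values) -> tuple[float, float]:
    """Mean and standard error (sd/sqrt(n), sample sd) of a 1-D sample."""
    values = np.asarray(values, float)
    n = len(values)
    if n == 0:
        raise ValueError("empty sample")
    se = float(np.std(values, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(values.mean()), se


# ----------------------------------------------------------- burden

def aberrant_burden(mesh: SurfaceMesh, ecap_values: np.ndarray,
                    delta: float = 0.10, weighting: str = "area",
                    include: np.ndarray | None = None) -> float:
    """Percent of wall area whose ECAP exceeds (1 + delta) x its wall mean.

    "Above 10% of the average" is read as 10% above the wall-mean ECAP
    (threshold 1.10 x mean); reading it as 0.10 x mean would flag nearly
    the whole wall.  Undefined (NaN) ECAP points are excluded from both
    the mean and the area.  Invariant to any positive rescaling of ECAP,
    so it is the same for raw and normalized fields.
    """
    ecap_values = np.asarray(ecap_values, float)
    if ecap_values.shape[0] != mesh.n_vertices:
        raise ValueError("ecap field length does not match mesh")
    ok = np.isfinite(ecap_values)
    if include is not None:
        ok &= np.asarray(include, bool)
    if not ok.any():
        raise ValueError("no included vertices with defined ECAP")
    if weighting == "area":
        w = compute_area_weights(mesh).per_vertex_area
    elif weighting == "count":
        w = np.ones(mesh.n_vertices)
    else:
        raise ValueError("weighting must be 'area' or 'count'")
    total = float(w[ok].sum())
    if total <= 0:
        raise ValueError("included vertices carry no area")
    mean = float((w[ok] * ecap_values[ok]).sum()) / total
    threshold = (1.0 + delta) * mean
    above = ok & (ecap_values > threshold)
    return 100.0 * float(w[above].sum()) / total


# ----------------------------------------------------------- region tests

@dataclass
class GroupStats:
    n: int
    mean: float
    se: float
    normality_p: float


@dataclass
class MetricComparison:
    fibrotic: GroupStats
    non_fibrotic: GroupStats
    test_used: str      # "mann_whitney_u" | "t_test"
    p_value: float
    significant: bool


@dataclass
class RegionComparison:
    """Fibrotic vs non-fibrotic comparison for a set of metrics."""

    metrics: dict            # name -> MetricComparison
    n_fibrotic: int
    n_non_fibrotic: int
    n_excluded: int
    alpha: float = ALPHA_DEFAULT


def _ks_normality_p(values: np.ndarray) -> float:
    """One-sample KS test of z-scored values against the standard normal."""
    sd = values.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return 0.0
    z = (values - values.mean()) / sd
    return float(sps.kstest(z, "norm").pvalue)


def region_compare(values: np.ndarray, mask: FibrosisMask,
                   alpha: float = ALPHA_DEFAULT,
                   force_test: str | None = None) -> MetricComparison:
    """Compare one metric between fibrotic and non-fibrotic vertices.

    NaN values are dropped from their region before testing.  Pass
    ``force_test`` ("mann_whitney_u" or "t_test") to bypass the
    normality-based selection.
    """
    values = np.asarray(values, float)
    if values.shape[0] != mask.n_vertices:
        raise ValueError("values length does not match mask")
    fib = values[mask.fibrotic]
    non = values[mask.non_fibrotic]
    fib = fib[np.isfinite(fib)]
    non = non[np.isfinite(non)]
    if len(fib) < 2 or len(non) < 2:
        raise ValueError(f"each region needs at least 2 points "
                         f"(fibrotic n={len(fib)}, non-fibrotic n={len(non)})")
    p_fib = _ks_normality_p(fib)
    p_non = _ks_normality_p(non)
    if force_test is not None:
        test = force_test
    elif p_fib < alpha or p_non < alpha:
        test = "mann_whitney_u"
    else:
        test = "t_test"
    if test == "mann_whitney_u":
        p = float(sps.mannwhitneyu(fib, non, alternative="two-sided").pvalue)
    elif test == "t_test":
        p = float(sps.ttest_ind(fib, non, equal_var=False).pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    mf, sf = mean_se(fib)
    mn, sn = mean_se(non)
    return MetricComparison(
        fibrotic=GroupStats(len(fib), mf, sf, p_fib),
        non_fibrotic=GroupStats(len(non), mn, sn, p_non),
        test_used=test, p_value=p, significant=bool(p < alpha))


def compare_regions(fields: dict, mask: FibrosisMask,
                    alpha: float = ALPHA_DEFAULT) -> RegionComparison:
    """Run :func:`region_compare` for every named metric field."""
    comps = {name: region_compare(vals, mask, alpha=alpha)
             for name, vals in fields.items()}
    return RegionComparison(metrics=comps,
                            n_fibrotic=int(mask.fibrotic.sum()),
                            n_non_fibrotic=int(mask.non_fibrotic.sum()),
                            n_excluded=mask.n_excluded,
                            alpha=alpha)


# ----------------------------------------------------------- case / cohort

@dataclass
class CaseReport:
    """Everything reported for one case.

    ``region_means`` holds per-metric means used for cohort averaging
    (normalized TAWSS/ECAP/RRT, raw OSI): ``{metric: {"fibrotic": m,
    "non_fibrotic": m}}``.  Metadata-only reports (printed cohort tables)
    leave the comparison fields None.
    """

    case_id: str
    af_type: str | None = None                   # "persistent" | "paroxysmal"
    fibrotic_burden_percent: float | None = None
    aberrant_burden_percent: float | None = None
    la_volume_ml: float | None = None
    n_surface_points: int | None = None
    region_means: dict | None = None
    region_means_raw: dict | None = None
    comparison: RegionComparison | None = None
    flags: dict = field(default_factory=dict)
    config: dict | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class CohortReport:
    n_cases: int
    metric_summary: dict        # metric -> region -> {mean, se}; + p_value/test
    group_summary: dict         # quantity -> group -> {mean, se, n}
    regression: dict | None     # slope/intercept/r_squared or {"error": ...}

    def to_dict(self) -> dict:
        return asdict(self)


def linear_fit_r2(x, y) -> tuple[float, float, float]:
    """Ordinary least squares of y on x: (slope, intercept, R^2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 (x, y) points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; linear fit undefined")
    res = sps.linregress(x, y)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:      # constant y: the fit explains nothing
        return float(res.slope), float(res.intercept), 0.0
    ss_res = float(((y - (res.slope * x + res.intercept)) ** 2).sum())
    return float(res.slope), float(res.intercept), 1.0 - ss_res / ss_tot


def _paired_test(fib: np.ndarray, non: np.ndarray,
                 alpha: float) -> tuple[str, float]:
    diff = fib - non
    if np.allclose(diff, 0):
        return "t_test", 1.0
    if _ks_normality_p(diff) < alpha:
        try:
            p = float(sps.wilcoxon(fib, non).pvalue)
            return "wilcoxon_signed_rank", p
        except ValueError:
            return "wilcoxon_signed_rank", 1.0
    p = float(sps.ttest_rel(fib, non).pvalue)
    return "t_test", p


def _group_stats(values: list[float]) -> dict:
    m, s = mean_se(values)
    return {"mean": m, "se": s, "n": len(values)}


def cohort_summary(cases: list[CaseReport],
                   alpha: float = ALPHA_DEFAULT) -> CohortReport:
    """Aggregate per-case reports into a cohort report.

    Metric region means are averaged across cases (not pooled over
    points), each metric compared between regions with a paired test
    across cases.  Fibrotic and aberrant burden and LA volume are
    summarized overall and by AF type.  When at least 3 cases carry both
    burdens and fibrotic burden is not constant, aberrant burden is
    regressed on fibrotic burden.
    """
    if len(cases) < 2:
        raise ValueError("a cohort needs at least 2 cases")

    metric_summary: dict = {}
    with_means = [c for c in cases if c.region_means]
    if with_means:
        keysets = {tuple(sorted(c.region_means)) for c in with_means}
        if len(keysets) > 1:
            raise ValueError("cases report inconsistent metric sets")
        for metric in with_means[0].region_means:
            fib = np.array([c.region_means[metric]["fibrotic"] for c in with_means])
            non = np.array([c.region_means[metric]["non_fibrotic"] for c in with_means])
            test, p = _paired_test(fib, non, alpha)
            mf, sf = mean_se(fib)
            mn, sn = mean_se(non)
            metric_summary[metric] = {
                "fibrotic": {"mean": mf, "se": sf},
                "non_fibrotic": {"mean": mn, "se": sn},
                "test_used": test, "p_value": p,
                "significant": bool(p < alpha)}

    group_summary: dict = {}
    for quantity, attr in (("fibrotic_burden_percent", "fibrotic_burden_percent"),
                           ("aberrant_burden_percent", "aberrant_burden_percent"),
                           ("la_volume_ml", "la_volume_ml")):
        have = [c for c in cases if getattr(c, attr) is not None]
        if not have:
            continue
        entry = {"overall": _group_stats([getattr(c, attr) for c in have])}
        for af in ("persistent", "paroxysmal"):
            sub = [getattr(c, attr) for c in have if c.af_type == af]
            if sub:
                entry[af] = _group_stats(sub)
        group_summary[quantity] = entry

    regression = None
    both = [c for c in cases if c.fibrotic_burden_percent is not None
            and c.aberrant_burden_percent is not None]
    if len(both) >= 3:
        x = [c.fibrotic_burden_percent for c in both]
        y = [c.aberrant_burden_percent for c in both]
        try:
            slope, intercept, r2 = linear_fit_r2(x, y)
            regression = {"slope": slope, "intercept": intercept,
                          "r_squared": r2, "n": len(both)}
        except ValueError as exc:
            regression = {"error": str(exc), "n": len(both)}

    return CohortReport(n_cases=len(cases), metric_summary=metric_summary,
                        group_summary=group_summary, regression=regression)
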