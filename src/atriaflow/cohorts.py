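"""Reference cohort metadata for the eight-patient AF analysis.

Per-case metadata of the clinical cohort this pipeline was designed
around: four persistent and four paroxysmal atrial-fibrillation
patients with their LGE-MRI fibrotic burden, left-atrial volume and
hemodynamic-model surface point count.  These printed values serve as
inputs for cohort-level descriptive statistics and for the regression of
aberrant hemodynamic burden on fibrotic burden; the underlying images
and flow solutions are not distributable, so per-point fields for these
cases cannot be recomputed here.
"""

from __future__ import annotations

from .stats import CaseReport

__all__ = ["AF_COHORT_EIGHT", "ABERRANT_BURDEN_PERCENT", "reference_cohort"]

# case id -> (AF type, fibrotic burden %, LA volume ml, wall surface points)
AF_COHORT_EIGHT = {
    "case1": ("persistent", 9.2168, 190.504, 40699),
    "case2": ("persistent", 17.768, 265.038, 55573),
    "case3": ("persistent", 16.927, 236.593, 49044),
    "case4": ("persistent", 6.0026, 188.645, 41797),
    "case5": ("paroxysmal", 13.6179, 111.66, 34098),
    "case6": ("paroxysmal", 13.4968, 125.988, 35336),
    "case7": ("paroxysmal", 11.024, 92.1394, 27563),
    "case8": ("paroxysmal", 24.8468, 59.7183, 19338),
}

# percent of the wall exposed to high ECAP, reported for the extreme cases
ABERRANT_BURDEN_PERCENT = {
    "case4": 9.4,
    "case2": 18.9,
    "case8": 18.5,
}


def reference_cohort(with_aberrant: bool = False) -> list[CaseReport]:
    """Metadata-only :class:`CaseReport` objects for the reference cohort.

    With ``with_aberrant=True`` the three cases with a published
    high-ECAP area fraction carry it, enabling the burden regression on
    that subset.
    """
    reports = []
    for cid, (af, fib, vol, npts) in AF_COHORT_EIGHT.items():
        ab = ABERRANT_BURDEN_PERCENT.get(cid) if with_aberrant else None
        reports.append(CaseReport(case_id=cid, af_type=af,
                                  fibrotic_burden_percent=fib,
                                  aberrant_burden_percent=ab,
                                  la_volume_ml=vol, n_surface_points=npts))
    return reports
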