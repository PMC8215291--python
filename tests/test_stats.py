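"""Burden quantification, region tests and cohort aggregation."""

import itertools

import numpy as np
import pytest

from atriaflow import (aberrant_burden, cohort_summary, linear_fit_r2,
                       mean_se, region_compare)
from atriaflow.cohorts import reference_cohort
from atriaflow.fibrosis import FibrosisMask
from atriaflow.stats import CaseReport
from conftest import icosphere


def exact_mwu_two_sided(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all rank splits."""
    pooled = np.concatenate([x, y])
    m = len(x)
    def u_stat(xs, ys):
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in xs for yi in ys)
    u_obs = u_stat(x, y)
    mn = m * len(y)
    hi = max(u_obs, mn - u_obs)
    us = np.array([u_stat(pooled[list(idx)],
                          np.delete(pooled, list(idx)))
                   for idx in itertools.combinations(range(len(pooled)), m)])
    # two-sided: double the upper tail (the null U distribution is symmetric)
    return float(min(1.0, 2.0 * np.mean(us >= hi)))


def make_mask(n_fib, n_non):
    fib = np.zeros(n_fib + n_non, bool)
    fib[:n_fib] = True
    return FibrosisMask(fibrotic=fib)


class TestAberrantBurden:
    def test_uniform_field_is_zero(self, sphere3):
        assert aberrant_burden(sphere3, np.full(sphere3.n_vertices, 2.0)) == 0.0

    def test_constructed_ten_percent(self):
        # 10% of area at ECAP 10, 90% at 1: mean 1.9, threshold 2.09 -> 10%
        mesh = icosphere(3)
        n = mesh.n_vertices
        field = np.ones(n)
        # pick vertices adding up to ~10% of the count (uniform-ish sphere)
        k = n // 10
        field[:k] = 10.0
        burden = aberrant_burden(mesh, field, delta=0.10, weighting="count")
        assert burden == pytest.approx(100.0 * k / n, abs=1e-9)

    def test_delta_monotone(self, sphere3, rng):
        field = rng.lognormal(size=sphere3.n_vertices)
        b1 = aberrant_burden(sphere3, field, delta=0.10)
        b2 = aberrant_burden(sphere3, field, delta=0.20)
        assert b2 <= b1

    def test_scale_invariant(self, sphere3, rng):
        field = rng.lognormal(size=sphere3.n_vertices)
        assert aberrant_burden(sphere3, field) == \
            pytest.approx(aberrant_burden(sphere3, 7.3 * field))

    def test_nan_excluded(self, sphere3, rng):
        field = rng.lognormal(size=sphere3.n_vertices)
        field[:5] = np.nan
        assert 0.0 <= aberrant_burden(sphere3, field) <= 100.0

    def test_all_undefined_rejected(self, sphere3):
        with pytest.raises(ValueError):
            aberrant_burden(sphere3, np.full(sphere3.n_vertices, np.nan))


class TestRegionCompare:
    def test_tiny_exact_mwu(self):
        values = np.array([1.0, 2.0, 3.0, 4.0])
        comp = region_compare(values, make_mask(2, 2),
                              force_test="mann_whitney_u")
        assert comp.p_value == pytest.approx(1 / 3, rel=1e-12)
        assert comp.fibrotic.mean == 1.5
        assert comp.non_fibrotic.mean == 3.5

    @pytest.mark.parametrize("m,n,seed", [(3, 5, 0), (4, 4, 1), (8, 6, 2),
                                          (5, 8, 3)])
    def test_matches_enumeration_oracle(self, m, n, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=m + n)  # continuous: ties almost surely absent
        comp = region_compare(values, make_mask(m, n),
                              force_test="mann_whitney_u")
        expected = exact_mwu_two_sided(values[:m], values[m:])
        assert comp.p_value == pytest.approx(expected, rel=1e-9)

    def test_identical_multisets_null(self):
        half = np.arange(60, dtype=float)
        values = np.concatenate([half, half])
        comp = region_compare(values, make_mask(60, 60),
                              force_test="mann_whitney_u")
        assert comp.p_value > 0.99

    def test_shifted_ecap_detected_at_scale(self):
        rng = np.random.default_rng(42)
        non = rng.normal(1.0, 1.0, 5000)
        fib = rng.normal(1.5, 1.0, 5000)  # +0.5 SD shift
        comp = region_compare(np.concatenate([fib, non]), make_mask(5000, 5000))
        assert comp.p_value < 1e-3
        assert comp.fibrotic.mean > comp.non_fibrotic.mean
        assert comp.test_used in ("mann_whitney_u", "t_test")

    def test_monotone_rescaling_invariance_under_mwu(self, rng):
        values = rng.normal(size=40)
        mask = make_mask(18, 22)
        p1 = region_compare(values, mask, force_test="mann_whitney_u").p_value
        p2 = region_compare(np.exp(values), mask,
                            force_test="mann_whitney_u").p_value
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_singleton_region_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            region_compare(np.arange(4.0), make_mask(1, 3))

    def test_normality_selects_t_test_for_gaussian(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=60)
        comp = region_compare(values, make_mask(30, 30))
        assert comp.test_used == "t_test"


class TestCohortSummary:
    def test_reference_burden_and_volume_descriptives(self):
        report = cohort_summary(reference_cohort())
        g = report.group_summary
        fib = g["fibrotic_burden_percent"]
        assert fib["overall"]["mean"] == pytest.approx(14.11, abs=0.01)
        assert fib["overall"]["se"] == pytest.approx(2.05, abs=0.01)
        assert fib["persistent"]["mean"] == pytest.approx(12.48, abs=0.01)
        assert fib["persistent"]["se"] == pytest.approx(2.89, abs=0.01)
        assert fib["paroxysmal"]["mean"] == pytest.approx(15.75, abs=0.01)
        assert fib["paroxysmal"]["se"] == pytest.approx(3.09, abs=0.01)
        vol = g["la_volume_ml"]
        assert vol["overall"]["mean"] == pytest.approx(158.79, abs=0.01)
        assert vol["overall"]["se"] == pytest.approx(25.63, abs=0.01)
        assert vol["persistent"]["mean"] == pytest.approx(220.20, abs=0.01)
        assert vol["persistent"]["se"] == pytest.approx(18.61, abs=0.01)
        assert vol["paroxysmal"]["mean"] == pytest.approx(97.38, abs=0.01)
        assert vol["paroxysmal"]["se"] == pytest.approx(14.34, abs=0.01)

    def test_two_identical_cases_have_zero_se(self):
        case = CaseReport(case_id="a", af_type="persistent",
                          fibrotic_burden_percent=10.0, la_volume_ml=100.0,
                          region_means={"tawss": {"fibrotic": 0.9,
                                                  "non_fibrotic": 1.1}})
        case2 = CaseReport(**{**case.__dict__, "case_id": "b"})
        report = cohort_summary([case, case2])
        assert report.group_summary["fibrotic_burden_percent"]["overall"]["se"] == 0.0
        assert report.metric_summary["tawss"]["fibrotic"]["se"] == 0.0

    def test_duplicated_cases_regression_reported_as_error(self):
        cases = [CaseReport(case_id=str(i), fibrotic_burden_percent=10.0,
                            aberrant_burden_percent=float(i))
                 for i in range(3)]
        report = cohort_summary(cases)
        assert "error" in report.regression
        assert "constant" in report.regression["error"]

    def test_inconsistent_metric_sets_rejected(self):
        a = CaseReport(case_id="a", region_means={"tawss": {"fibrotic": 1,
                                                            "non_fibrotic": 1}})
        b = CaseReport(case_id="b", region_means={"osi": {"fibrotic": 1,
                                                          "non_fibrotic": 1}})
        with pytest.raises(ValueError, match="inconsistent"):
            cohort_summary([a, b])

    def test_single_case_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            cohort_summary([CaseReport(case_id="only")])


class TestLinearFit:
    def test_perfect_line(self):
        slope, intercept, r2 = linear_fit_r2([0, 1, 2], [0, 1, 2])
        assert (slope, intercept, r2) == pytest.approx((1.0, 0.0, 1.0))

    def test_constant_y_gives_zero_r2(self):
        slope, intercept, r2 = linear_fit_r2([0, 1, 2], [5, 5, 5])
        assert slope == pytest.approx(0.0)
        assert r2 == pytest.approx(0.0)

    def test_three_reference_pairs_match_hand_ols(self):
        # (fibrosis %, high-ECAP area %) for the extreme reference cases;
        # expected values frozen from a closed-form OLS computed by hand
        x = [6.0026, 17.768, 24.8468]
        y = [9.4, 18.9, 18.5]
        slope, intercept, r2 = linear_fit_r2(x, y)
        assert slope == pytest.approx(0.5158249444339755, rel=1e-12)
        assert intercept == pytest.approx(7.24064411549188, rel=1e-12)
        assert r2 == pytest.approx(0.8350575139594982, rel=1e-12)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            linear_fit_r2([1, 1, 1], [0, 1, 2])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            linear_fit_r2([0, 1], [0, 1])


def test_mean_se_closed_form():
    m, s = mean_se([1.0, 2.0, 3.0, 4.0])
    assert m == 2.5
    assert s == pytest.approx(np.std([1, 2, 3, 4], ddof=1) / 2)
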