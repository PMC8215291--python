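"""TAWSS/OSI/ECAP/RRT quadrature against closed forms and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atriaflow import (WSSVectorSeries, analytic_sinusoid_oracle,
                       compute_metrics, ecap, n_frames_for_cycle,
                       normalize_by_mean, oscillatory_shear_index, rrt,
                       time_average_wss, uniform_times)

T = 0.92
EX = np.array([1.0, 0.0, 0.0])


def series_from_waveform(w, direction=EX, cycle_length=T):
    """Single-point series tau(t) = w(t) * direction."""
    tau = np.asarray(w, float)[:, None, None] * np.asarray(direction)[None, None, :]
    return WSSVectorSeries(tau=tau, cycle_length=cycle_length)


def sinusoid_series(amplitude=1.0, offset=0.0, n_frames=92):
    t = uniform_times(n_frames, T)
    return series_from_waveform(offset + amplitude * np.sin(2 * np.pi * t / T))


class TestTAWSS:
    def test_constant_vector(self):
        s = series_from_waveform(np.full(92, 0.5))
        assert time_average_wss(s)[0] == pytest.approx(0.5, abs=1e-12)

    def test_sinusoid_matches_closed_form(self):
        tawss = time_average_wss(sinusoid_series())[0]
        assert tawss == pytest.approx(2 / np.pi, abs=1e-3)

    def test_zero_series(self):
        s = series_from_waveform(np.zeros(92))
        assert time_average_wss(s)[0] == 0.0

    def test_nonuniform_times_constant(self):
        t = np.sort(np.random.default_rng(1).uniform(0, T, 20))
        s = WSSVectorSeries(np.ones((20, 1, 1)) * EX, times=t, cycle_length=T)
        assert time_average_wss(s)[0] == pytest.approx(1.0, abs=1e-12)

    def test_nonfinite_rejected_with_location(self):
        tau = np.zeros((4, 2, 3))
        tau[2, 1, 0] = np.nan
        with pytest.raises(ValueError, match="frame 2, point 1"):
            WSSVectorSeries(tau=tau)


class TestOSI:
    def test_constant_direction_is_zero(self):
        s = series_from_waveform(np.full(92, 0.7))
        assert oscillatory_shear_index(s)[0] == 0.0

    def test_full_reversal_is_half(self):
        # equal positive and negative lobes: 180 degree direction change
        w = np.where(np.arange(92) < 46, 1.0, -1.0)
        assert oscillatory_shear_index(series_from_waveform(w))[0] == \
            pytest.approx(0.5, abs=1e-12)

    def test_three_quarter_cycle_gives_quarter(self):
        # |int tau| = T/2, int |tau| = T  ->  0.5 * (1 - 0.5) = 0.25
        w = np.where(np.arange(92) < 69, 1.0, -1.0)
        assert oscillatory_shear_index(series_from_waveform(w))[0] == \
            pytest.approx(0.25, abs=1e-12)

    def test_zero_flow_convention(self):
        s = series_from_waveform(np.zeros(92))
        assert oscillatory_shear_index(s)[0] == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_bounds_on_random_series(self, seed):
        rng = np.random.default_rng(seed)
        tau = rng.normal(size=(12, 5, 3))
        osi = oscillatory_shear_index(WSSVectorSeries(tau=tau))
        assert np.all(osi >= 0.0)
        assert np.all(osi <= 0.5)


class TestECAPRRT:
    def test_ecap_ratio(self):
        assert ecap(np.array([0.5]), np.array([0.25]))[0] == pytest.approx(0.5)

    def test_ecap_zero_osi(self):
        assert ecap(np.array([2.0]), np.array([0.0]))[0] == 0.0

    def test_ecap_undefined_where_tawss_zero(self):
        assert np.isnan(ecap(np.array([0.0]), np.array([0.1]))[0])

    def test_rrt_constant_flow(self):
        out, capped = rrt(np.array([1.0]), np.array([0.0]))
        assert out[0] == pytest.approx(1.0)
        assert not capped[0]

    def test_rrt_equals_reciprocal_mean_vector(self):
        out, _ = rrt(np.array([1.0]), np.array([0.25]))
        assert out[0] == pytest.approx(2.0)  # 1 / |time-mean| = 1 / 0.5

    def test_rrt_capped_at_pure_reversal(self):
        out, capped = rrt(np.array([1.0]), np.array([0.5]), cap=1e6)
        assert capped[0]
        assert out[0] == 1e6

    def test_rrt_identity_where_uncapped(self, rng):
        tau = rng.normal(size=(30, 40, 3))
        s = WSSVectorSeries(tau=tau)
        tawss = time_average_wss(s)
        osi = oscillatory_shear_index(s)
        out, capped = rrt(tawss, osi)
        # 1 / ((1 - 2 OSI) TAWSS) == 1 / |time-mean vector|
        mean_vec = np.einsum("f,fpc->pc", s.quadrature_weights(), tau) / T
        expected = 1.0 / np.linalg.norm(mean_vec, axis=1)
        np.testing.assert_allclose(out[~capped], expected[~capped], rtol=1e-9)

    def test_monotonicity_in_osi_and_tawss(self):
        e1 = ecap(np.array([1.0]), np.array([0.1]))
        e2 = ecap(np.array([1.0]), np.array([0.2]))
        e3 = ecap(np.array([2.0]), np.array([0.1]))
        assert e2 > e1 > e3
        r1, _ = rrt(np.array([1.0]), np.array([0.1]))
        r2, _ = rrt(np.array([1.0]), np.array([0.2]))
        r3, _ = rrt(np.array([2.0]), np.array([0.1]))
        assert r2 > r1 > r3

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ecap(np.zeros(3), np.zeros(4))
        with pytest.raises(ValueError):
            rrt(np.zeros(3), np.zeros(4))


class TestNormalization:
    def test_count_weighting(self):
        np.testing.assert_allclose(normalize_by_mean(np.array([1.0, 2, 3])),
                                   [0.5, 1.0, 1.5])

    def test_idempotent(self, rng):
        f = rng.uniform(0.1, 3, 100)
        once = normalize_by_mean(f)
        np.testing.assert_allclose(normalize_by_mean(once), once, rtol=1e-12)

    @pytest.mark.parametrize("k", [0.1, 3.0, 1e4])
    def test_scale_invariant(self, rng, k):
        f = rng.uniform(0.1, 3, 100)
        np.testing.assert_allclose(normalize_by_mean(k * f),
                                   normalize_by_mean(f), rtol=1e-12)

    def test_weighted_mean_is_one(self, rng):
        f = rng.uniform(0.1, 3, 100)
        w = rng.uniform(0.5, 2, 100)
        out = normalize_by_mean(f, weights=w)
        assert np.average(out, weights=w) == pytest.approx(1.0, abs=1e-9)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            normalize_by_mean(np.array([-1.0, -2.0]))


class TestInvariantsAndOracle:
    def test_rotation_invariance(self, rng):
        tau = rng.normal(size=(20, 30, 3))
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        m1 = compute_metrics(WSSVectorSeries(tau=tau), normalize=False)
        m2 = compute_metrics(WSSVectorSeries(tau=tau @ q.T), normalize=False)
        for name in ("tawss", "osi", "rrt"):
            np.testing.assert_allclose(getattr(m1, name), getattr(m2, name),
                                       rtol=1e-9)

    @pytest.mark.parametrize("amplitude,offset", [
        (1.0, 0.0), (1.0, 0.5), (2.0, 3.0), (1.5, 0.7)])
    def test_quadrature_converges_to_analytic_oracle(self, amplitude, offset):
        exp_tawss, exp_osi = analytic_sinusoid_oracle(amplitude, offset)
        s = sinusoid_series(amplitude, offset, n_frames=92)
        assert time_average_wss(s)[0] == pytest.approx(exp_tawss, rel=1e-3)
        assert oscillatory_shear_index(s)[0] == pytest.approx(exp_osi, abs=1e-3)

    def test_oracle_closed_forms(self):
        # offset 0: TAWSS = 2A/pi, full reversal
        tawss, osi = analytic_sinusoid_oracle(2.0, 0.0)
        assert tawss == pytest.approx(4 / np.pi, rel=1e-12)
        assert osi == 0.5
        # offset >= amplitude: no sign change
        tawss, osi = analytic_sinusoid_oracle(1.0, 3.0)
        assert (tawss, osi) == (3.0, 0.0)
        # offset = amplitude / 2: piecewise integral, frozen from the
        # symbolic closed form
        tawss, osi = analytic_sinusoid_oracle(1.0, 0.5)
        assert tawss == pytest.approx(0.7179955620884587, rel=1e-12)
        assert osi == pytest.approx(0.15180843280867046, rel=1e-12)

    def test_refinement_improves_quadrature(self):
        errs = [abs(time_average_wss(sinusoid_series(n_frames=n))[0] - 2 / np.pi)
                for n in (46, 92, 368)]
        assert errs[0] > errs[1] > errs[2]


class TestBookkeeping:
    def test_cycle_frame_count(self):
        assert n_frames_for_cycle(0.92, 0.01) == 92

    def test_incompatible_resolution_rejected(self):
        with pytest.raises(ValueError):
            n_frames_for_cycle(0.925, 0.01)

    def test_series_validation(self):
        with pytest.raises(ValueError, match="at least 2"):
            WSSVectorSeries(tau=np.zeros((1, 2, 3)))
        with pytest.raises(ValueError, match="increasing"):
            WSSVectorSeries(tau=np.zeros((3, 2, 3)), times=[0.0, 0.5, 0.4])
        with pytest.raises(ValueError, match="cycle_length"):
            WSSVectorSeries(tau=np.zeros((2, 1, 3)), times=[0.0, 0.92])

    def test_quadrature_weights_sum_to_cycle(self, rng):
        t = np.sort(rng.uniform(0, T, 15))
        s = WSSVectorSeries(np.zeros((15, 1, 3)), times=t, cycle_length=T)
        assert s.quadrature_weights().sum() == pytest.approx(T, rel=1e-12)
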