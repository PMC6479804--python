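"""DSS discrete curvature: examples, invariants, and exact agreement with a
literal nested-loop transcription of the search procedure."""

import math

import numpy as np
import pytest

from ldasg import (
    CurvatureParams,
    SignalSeries,
    centered_slope_variation,
    curvature_at,
    curvature_profile,
    dss_search,
    slope_angle,
)

# ---------------------------------------------------------------------------
# Brute-force oracle: literal transcription of the DSS search, no vectorisation
# ---------------------------------------------------------------------------


def brute_theta(x, i, k):
    # np.arctan, not math.atan: the production code computes angles through
    # the numpy ufunc, and the two libraries may differ in the last ulp
    return np.arctan(abs(x[i] - x[i - k]) / k)


def brute_delta2(x, j):
    """delta_{j,2}; None when a needed sample is out of range."""
    n = len(x)
    if j - 3 < 0 or j + 1 > n - 1:
        return None
    return brute_theta(x, j + 1, 2) - brute_theta(x, j - 1, 2)


def brute_curvature(x, i, km, delta):
    kb = 0
    for k in range(1, km + 1):
        d = brute_delta2(x, i - k)
        if d is None or not (-delta <= d <= delta):
            break
        kb = k
    kb = max(kb, 1)
    kf = 0
    for k in range(1, km + 1):
        d = brute_delta2(x, i + k)
        if d is None or not (-delta <= d <= delta):
            break
        kf = k
    kf = max(kf, 1)
    db = x[i] - x[i - kb]
    df = x[i] - x[i + kf]
    Lb = np.sqrt(db * db + kb * kb)
    Lf = np.sqrt(df * df + kf * kf)
    tb = brute_theta(x, i, kb)
    tf = np.arctan(abs(x[i] - x[i + kf]) / kf)
    return (Lb + Lf) * (tb + tf) / (4 * Lb * Lf)


# ---------------------------------------------------------------------------


class TestSlopeAngle:
    def test_unit_rise(self):
        x = SignalSeries(np.array([0.0, 1.0, 1.0]))
        assert slope_angle(x, 1, 1) == pytest.approx(math.pi / 4)

    def test_flat(self):
        x = SignalSeries(np.zeros(5))
        assert slope_angle(x, 3, 2) == 0.0

    def test_fall_uses_absolute_value(self):
        x = SignalSeries(np.array([1.0, 0.0]))
        assert slope_angle(x, 1, 1) == pytest.approx(math.pi / 4)

    def test_out_of_range(self):
        x = SignalSeries(np.zeros(5))
        with pytest.raises(IndexError):
            slope_angle(x, 1, 2)


class TestCenteredVariation:
    def test_straight_line_cancels(self):
        x = SignalSeries(1.7 * np.arange(10) + 3)
        assert centered_slope_variation(x, 5, 2) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_kink(self):
        # theta[4,2] = atan(|x4-x2|/2) = atan(1/2); theta[2,2] = 0
        x = SignalSeries(np.array([0.0, 0.0, 0.0, 0.0, 1.0, 2.0]))
        assert centered_slope_variation(x, 3, 2) == pytest.approx(math.atan(0.5))

    def test_equal_backward_angles_cancel(self):
        # theta[4,2] = |x4-x2|/2 and theta[2,2] = |x2-x0|/2 are equal by
        # construction here, so the centred variation vanishes
        x = SignalSeries(np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0]))
        assert centered_slope_variation(x, 3, 2) == pytest.approx(0.0, abs=1e-12)

    def test_out_of_range(self):
        x = SignalSeries(np.zeros(6))
        with pytest.raises(IndexError):
            centered_slope_variation(x, 2, 2)


class TestDSSSearch:
    def test_straight_line_grows_to_km(self):
        x = SignalSeries(0.6 * np.arange(40))
        r = dss_search(x, 20, CurvatureParams(km=10, delta=0.05))
        assert r.kb == r.kf == 10
        assert r.theta_b == pytest.approx(math.atan(0.6))
        assert r.theta_f == pytest.approx(math.atan(0.6))

    def test_constant_signal(self):
        x = SignalSeries(np.full(30, 4.0))
        r = dss_search(x, 15, CurvatureParams(km=5, delta=0.05))
        assert r.Lb == r.Lf == 5.0
        assert r.theta_b == r.theta_f == 0.0

    def test_corner_stops_where_predicate_fails(self):
        # slopes 0 then 1: scan from the corner must stop at the first s
        # whose centred variation exceeds delta, matching the brute force
        x = np.concatenate([np.zeros(20), np.arange(1, 21, dtype=float)])
        sig = SignalSeries(x)
        params = CurvatureParams(km=10, delta=0.05)
        i = 19
        r = dss_search(sig, i, params)
        # recompute the stopping points literally
        for name, step, k_got in (("back", -1, r.kb), ("fwd", +1, r.kf)):
            k_expect = 0
            for k in range(1, params.km + 1):
                d = brute_delta2(x, i + step * k)
                if d is None or abs(d) > params.delta:
                    break
                k_expect = k
            assert k_got == max(k_expect, 1), name

    def test_minimum_length_accepted_unconditionally(self):
        x = SignalSeries(np.array([0.0, 5.0, -5.0, 5.0, -5.0, 5.0, -5.0, 0.0, 0.0]))
        r = dss_search(x, 4, CurvatureParams(km=5, delta=0.01))
        assert r.kb == 1 and r.kf == 1


class TestCurvatureValues:
    def test_constant_is_zero(self):
        x = SignalSeries(np.full(30, 1.0))
        assert curvature_at(x, 15, CurvatureParams()) == 0.0

    def test_step_edge_matches_hand_evaluation(self):
        x = np.concatenate([np.zeros(15), np.ones(15)])
        sig = SignalSeries(x)
        params = CurvatureParams(km=5, delta=0.05)
        i = 14
        assert curvature_at(sig, i, params) == pytest.approx(
            brute_curvature(x, i, params.km, params.delta), abs=0
        )

    def test_isolated_spike(self):
        x = np.zeros(41)
        x[20] = 1.0
        sig = SignalSeries(x)
        params = CurvatureParams(km=5, delta=0.05)
        at_spike = curvature_at(sig, 20, params)
        far_away = curvature_at(sig, 8, params)
        assert at_spike == pytest.approx(brute_curvature(x, 20, 5, 0.05))
        assert at_spike > 10 * max(far_away, 1e-12)
        assert far_away == 0.0


class TestProfile:
    def test_production_equals_brute_force_exactly(self, rng):
        # 200 random signals (smooth + noisy mixtures), every defined index
        for trial in range(200):
            n = int(rng.integers(12, 101))
            kind = trial % 3
            if kind == 0:
                x = rng.normal(0, 1, n)
            elif kind == 1:
                x = np.sin(np.arange(n) * rng.uniform(0.05, 0.5))
            else:
                x = np.cumsum(rng.normal(0, 0.2, n))
            km = int(rng.integers(2, 12))
            delta = float(rng.uniform(0.01, 0.5))
            params = CurvatureParams(km=km, delta=delta)
            prof = curvature_profile(SignalSeries(x), params, exclusion=0)
            lo, hi = prof.valid_range
            expected = [brute_curvature(x, i, km, delta) for i in range(lo, hi + 1)]
            assert np.array_equal(prof.values[lo : hi + 1], expected), (trial, n, km, delta)

    def test_profile_matches_pointwise_search(self, rng):
        x = SignalSeries(rng.normal(0, 1, 80))
        params = CurvatureParams(km=7, delta=0.2)
        prof = curvature_profile(x, params, exclusion=4)
        lo, hi = prof.valid_range
        for i in range(lo, hi + 1):
            assert prof.values[i] == curvature_at(x, i, params)

    def test_constant_profile_zero(self):
        prof = curvature_profile(SignalSeries(np.full(50, 3.0)), CurvatureParams(), exclusion=8)
        lo, hi = prof.valid_range
        assert np.all(prof.values[lo : hi + 1] == 0.0)
        assert prof.cmax == prof.cmin == 0.0
        assert np.all(np.isnan(prof.values[:lo])) and np.all(np.isnan(prof.values[hi + 1 :]))

    def test_linear_ramp_profile_uniform(self):
        # identical local geometry everywhere; restrict to the deep interior
        # where the DSS scan is not truncated by the array bounds
        params = CurvatureParams()
        prof = curvature_profile(SignalSeries(2.0 * np.arange(60)), params, exclusion=8)
        lo, hi = prof.valid_range
        vals = prof.values[lo + params.km : hi - params.km + 1]
        assert vals.size > 10
        assert np.allclose(vals, vals[0], atol=1e-12)

    def test_nonnegative_and_translation_invariant(self, rng):
        x = rng.normal(0, 1, 120)
        params = CurvatureParams(km=6, delta=0.3)
        p1 = curvature_profile(SignalSeries(x), params, exclusion=5)
        p2 = curvature_profile(SignalSeries(x + 17.3), params, exclusion=5)
        lo, hi = p1.valid_range
        assert np.all(p1.values[lo : hi + 1] >= 0)
        assert np.allclose(p1.values[lo : hi + 1], p2.values[lo : hi + 1], atol=1e-12, rtol=0)

    def test_amplitude_scaling_does_not_decrease_peak_curvature(self, rng):
        # holds while slope angles stay below saturation (peaks <= ~0.8
        # sample-units here); for very large amplitudes the angle terms
        # saturate at pi/2 while the DSS lengths keep growing, so the
        # estimator's peak response eventually decays by construction
        params = CurvatureParams(km=5, delta=0.1)
        for _ in range(100):
            n = 41
            center = 20
            width = rng.uniform(1.0, 4.0)
            amp = rng.uniform(0.05, 0.25)
            a = rng.uniform(1.0, 0.8 / amp)
            bump = amp * np.exp(-((np.arange(n) - center) ** 2) / (2 * width**2))
            c1 = curvature_at(SignalSeries(bump), center, params)
            c2 = curvature_at(SignalSeries(a * bump), center, params)
            assert c2 >= c1 - 1e-12

    def test_r_peak_colocation(self, ecg_fixture):
        clean, r_idx = ecg_fixture
        prof = curvature_profile(clean, CurvatureParams(), exclusion=8)
        half = int(0.5 * clean.sampling_rate * 60 / 72)
        for ri in r_idx:
            lo = max(prof.valid_range[0], ri - half)
            hi = min(prof.valid_range[1], ri + half)
            local_argmax = lo + int(np.nanargmax(prof.values[lo : hi + 1]))
            assert abs(local_argmax - ri) <= 3

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            curvature_profile(SignalSeries(np.zeros(7)), CurvatureParams(), exclusion=8)


class TestParams:
    @pytest.mark.parametrize("km,delta", [(1, 0.05), (5, 0.0), (5, -0.1)])
    def test_invalid_params(self, km, delta):
        with pytest.raises(ValueError):
            CurvatureParams(km=km, delta=delta)
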