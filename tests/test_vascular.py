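"""Vascular module: FMD arithmetic, shear rate, conductance, scaling check."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import vasoreact as vr
from vasoreact.errors import DomainError, InsufficientDataError


def make_trace(time, diameter, velocity, sample_rate=10.0, pre=30.0):
    return vr.FmdTrace(time=np.asarray(time, float),
                       diameter=np.asarray(diameter, float),
                       velocity=np.asarray(velocity, float),
                       sample_rate=sample_rate, pre_deflation_window=pre)


class TestScalarFormulas:
    @pytest.mark.parametrize("base, peak, expected", [
        (0.30, 0.33, 10.0),
        (0.25, 0.25, 0.0),
        (0.29, 0.32, (0.32 - 0.29) / 0.29 * 100),
    ])
    def test_fmd_percent(self, base, peak, expected):
        assert vr.fmd_percent(base, peak) == pytest.approx(expected, abs=1e-12)

    def test_fmd_percent_rejects_nonpositive_baseline(self):
        with pytest.raises(DomainError):
            vr.fmd_percent(0.0, 0.3)

    @pytest.mark.parametrize("v, d, expected", [
        (0.0, 0.4, 0.0),
        (10.0, 0.4, 10 * math.pi * 0.2**2 * 60),  # 75.398 ml/min
        (5.0, 0.2, 5 * math.pi * 0.1**2 * 60),    # 9.425 ml/min
    ])
    def test_blood_flow(self, v, d, expected):
        assert vr.blood_flow(v, d) == pytest.approx(expected, rel=1e-12)

    def test_blood_flow_printed_magnitudes(self):
        assert vr.blood_flow(10.0, 0.4) == pytest.approx(75.40, abs=0.01)
        assert vr.blood_flow(5.0, 0.2) == pytest.approx(9.42, abs=0.01)

    def test_blood_flow_rejects_reverse_flow(self):
        with pytest.raises(DomainError):
            vr.blood_flow(-1.0, 0.4)

    @pytest.mark.parametrize("v, d, expected", [
        (10.0, 0.4, 200.0),
        (0.0, 0.3, 0.0),
    ])
    def test_shear_rate(self, v, d, expected):
        assert vr.shear_rate(v, d) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(0.1, 100), st.floats(0.05, 1.0))
    def test_shear_rate_algebraic_inverse(self, v, d):
        sr = vr.shear_rate(v, d)
        assert sr * d / 8.0 == pytest.approx(v, rel=1e-12)

    @given(st.floats(0.1, 100), st.floats(0.05, 1.0), st.floats(1.1, 5.0))
    def test_flow_and_shear_scaling_laws(self, v, d, c):
        # flow is linear in v and quadratic in d; shear linear in v, ~1/d
        assert vr.blood_flow(c * v, d) == pytest.approx(c * vr.blood_flow(v, d), rel=1e-9)
        assert vr.blood_flow(v, c * d) == pytest.approx(c**2 * vr.blood_flow(v, d), rel=1e-9)
        assert vr.shear_rate(c * v, d) == pytest.approx(c * vr.shear_rate(v, d), rel=1e-9)
        assert vr.shear_rate(v, c * d) == pytest.approx(vr.shear_rate(v, d) / c, rel=1e-9)

    def test_normalized_fmd(self):
        assert vr.normalized_fmd(10.0, 5000.0) == pytest.approx(0.002)
        assert vr.normalized_fmd(0.0, 5000.0) == 0.0
        with pytest.raises(DomainError):
            vr.normalized_fmd(10.0, 0.0)

    def test_vascular_conductance_printed_values(self):
        assert vr.vascular_conductance(47.8, 101) == pytest.approx(0.47, abs=0.005)
        assert vr.vascular_conductance(116.9, 108) == pytest.approx(1.08, abs=0.005)
        assert vr.vascular_conductance(0.0, 90.0) == 0.0
        with pytest.raises(DomainError):
            vr.vascular_conductance(50.0, 0.0)


class TestBaselineAndPeak:
    def test_baseline_of_constant_trace(self):
        t = np.arange(-30, 120, 0.1)
        tr = make_trace(t, np.full(t.size, 0.30), np.full(t.size, 10.0))
        assert vr.baseline_diameter(tr) == pytest.approx(0.30, abs=1e-12)

    def test_baseline_is_arithmetic_mean(self):
        t = np.array([-3.0, -2.0, -1.0, -0.5, -0.1, 1.0, 2.0])
        d = np.array([0.29, 0.30, 0.31, 0.30, 0.30, 0.31, 0.30])
        tr = make_trace(t, d, np.full(t.size, 5.0), pre=3.0)
        assert vr.baseline_diameter(tr) == pytest.approx(np.mean(d[:5]), abs=1e-12)

    def test_baseline_noise_within_se_bound(self, rng):
        tr = vr.generate_fmd_trace(vr.FmdSimParams(
            baseline_diameter=0.30, noise_sd_diameter=0.002, seed=7))
        n = int(30 * tr.sample_rate)
        assert abs(vr.baseline_diameter(tr) - 0.30) < 3 * 0.002 / math.sqrt(n)

    def test_baseline_requires_pre_window(self):
        t = np.arange(0.1, 100, 0.1)
        tr = make_trace(t, np.full(t.size, 0.3), np.full(t.size, 5.0))
        with pytest.raises(InsufficientDataError):
            vr.baseline_diameter(tr)

    def test_peak_of_noiseless_trace_is_programmed(self, noiseless_trace):
        peak, ttp = vr.peak_diameter(noiseless_trace)
        assert peak == pytest.approx(0.33, abs=1e-12)
        assert ttp == pytest.approx(30.0, abs=1e-9)

    def test_monotone_decreasing_post_release_peaks_at_first_sample(self):
        t = np.arange(-30, 120, 0.5)
        d = np.where(t <= 0, 0.35, 0.35 - 1e-4 * t)
        tr = make_trace(t, d, np.full(t.size, 5.0), sample_rate=2.0)
        peak, ttp = vr.peak_diameter(tr, smooth_window=0.0)
        first_post = t[t > 0][0]
        assert ttp == first_post
        assert peak == pytest.approx(0.35 - 1e-4 * first_post)

    def test_peak_matches_exhaustive_scan_of_smoothed_series(self, rng):
        tr = vr.generate_fmd_trace(vr.FmdSimParams(
            noise_sd_diameter=0.003, noise_sd_velocity=2.0, seed=42))
        peak, ttp = vr.peak_diameter(tr, smooth_window=3.0)
        smooth = vr.vascular.smoothed_diameter(tr, 3.0)
        post = tr.time > 0
        # brute force: scan every post-deflation sample
        best_val, best_t = -np.inf, None
        for ti, di in zip(tr.time[post], smooth[post]):
            if di > best_val:
                best_val, best_t = di, ti
        assert peak == best_val
        assert ttp == best_t

    def test_peak_requires_post_samples(self):
        t = np.arange(-30, -0.1, 0.1)
        tr = make_trace(t, np.full(t.size, 0.3), np.full(t.size, 5.0))
        with pytest.raises(InsufficientDataError):
            vr.peak_diameter(tr)


class TestCumulativeShearRate:
    def test_constant_sr_rectangle(self):
        # SR = 200/s for 30 s -> 6000; exact grid so 0 and 30 s are samples
        t = (np.arange(1500) - 300) * 0.1
        d = np.full(t.size, 0.4)
        v = np.full(t.size, 10.0)  # SR = 8*10/0.4 = 200
        tr = make_trace(t, d, v)
        assert vr.cumulative_shear_rate(tr, 0.0, 30.0) == pytest.approx(6000.0, rel=1e-9)

    def test_linear_ramp_triangle(self):
        # SR ramps 0 -> 100 over 10 s: trapezoid is exact -> 500
        t = (np.arange(300) - 60) * 0.5
        d = np.full(t.size, 0.8)
        v = np.where((t >= 0) & (t <= 10), t, 0.0)  # SR = 8v/d = 10t
        tr = make_trace(t, d, v, sample_rate=2.0)
        assert vr.cumulative_shear_rate(tr, 0.0, 10.0) == pytest.approx(500.0, rel=1e-12)

    def test_equals_brute_force_trapezoid_oracle(self, rng):
        t = np.arange(-30, 120, 0.1)
        d = 0.3 + 0.02 * rng.random(t.size)
        v = 5.0 + 10.0 * rng.random(t.size)
        tr = make_trace(t, d, v)
        got = vr.cumulative_shear_rate(tr, 0.0, 40.0)
        # independent oracle: explicit sum of per-interval trapezoids
        mask = (t >= 0) & (t <= 40.0)
        y = 8.0 * v[mask] / d[mask]
        x = t[mask]
        oracle = sum(
            (y[i] + y[i + 1]) / 2.0 * (x[i + 1] - x[i]) for i in range(len(x) - 1)
        )
        assert got == pytest.approx(oracle, rel=1e-13)

    def test_ordering_error(self, noiseless_trace):
        with pytest.raises(DomainError):
            vr.cumulative_shear_rate(noiseless_trace, 30.0, 10.0)


class TestComposite:
    def test_noiseless_recovery_of_programmed_fmd(self, noiseless_trace):
        res = vr.analyze_trace(noiseless_trace)
        assert res.fmd_percent == pytest.approx(10.0, abs=1e-9)
        assert res.time_to_peak == pytest.approx(30.0, abs=1e-9)

    def test_null_effect_trace_gives_zero_fmd(self):
        tr = vr.generate_fmd_trace(vr.FmdSimParams(fmd_percent=0.0, seed=0))
        res = vr.analyze_trace(tr)
        assert res.fmd_percent == pytest.approx(0.0, abs=1e-9)

    def test_doubling_velocity_halves_normalized_fmd(self, noiseless_trace):
        res1 = vr.analyze_trace(noiseless_trace)
        doubled = vr.FmdTrace(
            time=noiseless_trace.time, diameter=noiseless_trace.diameter,
            velocity=2 * noiseless_trace.velocity,
            sample_rate=noiseless_trace.sample_rate,
            pre_deflation_window=noiseless_trace.pre_deflation_window)
        res2 = vr.analyze_trace(doubled)
        assert res2.fmd_percent == pytest.approx(res1.fmd_percent, rel=1e-9)
        assert res2.cumulative_sr == pytest.approx(2 * res1.cumulative_sr, rel=1e-9)
        assert res2.fmd_per_sr == pytest.approx(res1.fmd_per_sr / 2, rel=1e-9)


class TestAllometricScaling:
    def test_exact_proportionality_is_valid(self):
        base = np.array([0.26, 0.28, 0.30, 0.32, 0.34])
        res = vr.allometric_scaling_check(base, 1.1 * base)
        assert res.slope == pytest.approx(1.0, abs=1e-9)
        assert res.ci_low == pytest.approx(res.ci_high, abs=1e-9)
        assert res.ratio_scaling_valid

    def test_large_n_detects_sublinear_scaling(self, rng):
        base = rng.lognormal(np.log(0.30), 0.15, 200)
        peak = base**0.8 * np.exp(rng.normal(0, 0.002, 200))
        res = vr.allometric_scaling_check(base, peak)
        assert res.slope == pytest.approx(0.8, abs=0.01)
        assert res.ci_high < 1.0
        assert not res.ratio_scaling_valid

    def test_too_few_pairs_error(self):
        with pytest.raises(InsufficientDataError):
            vr.allometric_scaling_check([0.3, 0.31], [0.33, 0.34])

    def test_nonpositive_diameter_error(self):
        with pytest.raises(DomainError):
            vr.allometric_scaling_check([0.3, -0.1, 0.3], [0.33, 0.3, 0.33])


class TestFlowCurve:
    def test_constant_flow_auc_rectangle(self):
        # constant v and d: flow F over 120 s -> AUC = F * 2 (minutes)
        t = np.arange(-30, 120.001, 0.1)
        tr = make_trace(t, np.full(t.size, 0.4), np.full(t.size, 10.0))
        F = vr.blood_flow(10.0, 0.4)
        curve, auc = vr.hyperaemia_flow_curve([tr], bin_width=2.0)
        assert auc == pytest.approx(F * 2.0, rel=1e-9)

    def test_mean_of_identical_traces_is_idempotent(self, noiseless_trace):
        c1, a1 = vr.hyperaemia_flow_curve([noiseless_trace], 2.0)
        c2, a2 = vr.hyperaemia_flow_curve([noiseless_trace] * 2, 2.0)
        np.testing.assert_allclose(c2["flow_ml_min"], c1["flow_ml_min"], rtol=1e-12)
        assert a2 == pytest.approx(a1, rel=1e-12)

    def test_uniform_flow_scaling_scales_auc(self, noiseless_trace):
        scaled = vr.FmdTrace(
            time=noiseless_trace.time, diameter=noiseless_trace.diameter,
            velocity=0.71 * noiseless_trace.velocity,
            sample_rate=noiseless_trace.sample_rate,
            pre_deflation_window=noiseless_trace.pre_deflation_window)
        _, a_pre = vr.hyperaemia_flow_curve([noiseless_trace], 2.0)
        _, a_post = vr.hyperaemia_flow_curve([scaled], 2.0)
        assert a_post / a_pre == pytest.approx(0.71, rel=1e-9)

    def test_empty_input_error(self):
        with pytest.raises(InsufficientDataError):
            vr.hyperaemia_flow_curve([], 2.0)


class TestWindowedHemodynamics:
    @staticmethod
    def stream(hr, mapv, sv, flow, t_end=60.0):
        import pandas as pd
        t = np.arange(0, t_end, 0.5)
        return pd.DataFrame({
            "time_s": t,
            "heart_rate": np.broadcast_to(hr, t.shape).copy(),
            "map": np.broadcast_to(mapv, t.shape).copy(),
            "sv": np.broadcast_to(sv, t.shape).copy(),
            "blood_flow": np.broadcast_to(flow, t.shape).copy(),
        })

    def test_constant_stream_returns_constants(self):
        base, tail = vr.windowed_hemodynamics(self.stream(70.0, 100.0, 50.0, 60.0))
        for s in (base, tail):
            assert s.heart_rate == 70.0
            assert s.map == 100.0
            assert s.co == pytest.approx(3.5)  # sv*hr/1000
            assert s.bvc == pytest.approx(0.6)

    def test_baseline_vs_tail_percent_change(self):
        import pandas as pd
        t = np.arange(0, 90, 0.5)
        # step edges aligned with the averaging windows: baseline is
        # [0, 30] inclusive, tail is the last 10 s of the stream
        hr = np.where(t <= 30, 70.0, np.where(t >= t[-1] - 10, 83.0, 75.0))
        df = pd.DataFrame({"time_s": t, "heart_rate": hr,
                           "map": np.full(t.size, 100.0),
                           "sv": np.full(t.size, 50.0),
                           "blood_flow": np.full(t.size, 60.0)})
        base, tail = vr.windowed_hemodynamics(df)
        change = vr.percent_change(base.heart_rate, tail.heart_rate)
        assert change == pytest.approx((83 - 70) / 70 * 100, rel=1e-9)

    def test_short_stream_error(self):
        with pytest.raises(InsufficientDataError):
            vr.windowed_hemodynamics(self.stream(70, 100, 50, 60, t_end=20.0))
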