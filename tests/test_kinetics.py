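"""Milestone extraction: closed-form cases, identities, and recovery from synthesis."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import skew as sp_skew

from conftest import make_trace
from fluortrack.errors import NoInflowError, ValidationError
from fluortrack.kinetics import (
    compute_profile,
    detect_latency_end,
    fit_log_curve,
    group_mean_curves,
    profiles_to_frame,
)
from fluortrack.synth import GROUP_PRESETS, simulate_trace, true_profile

TIME_FIELDS = ["latency_end_time_s", "t_max_s", "t_half_s", "t100_s", "time_to_rise_s"]
INTENSITY_FIELDS = [
    "latency_end_intensity_gu",
    "f_max_gu",
    "rise_gu",
    "f_half_gu",
    "f100_gu",
    "fall100_gu",
    "final_intensity_gu",
]


class TestLatencyDetection:
    def test_step_trace_crossing_at_step(self):
        t = np.arange(0.0, 30.0)
        y = np.where(t < 12, 10.0, 40.0)
        t_le, i_le = detect_latency_end(make_trace(t, y))
        assert t_le == 12.0
        assert i_le == 40.0

    def test_constant_trace_no_inflow(self):
        t = np.arange(0.0, 30.0)
        with pytest.raises(NoInflowError):
            detect_latency_end(make_trace(t, np.full_like(t, 10.0)))

    def test_analytic_crossing_within_one_sample(self):
        params = replace(GROUP_PRESETS["control"], noise_sd_gu=0.0)
        trace, truth = simulate_trace(params, fps=30, duration_s=300)
        t_le, _ = detect_latency_end(trace)
        assert abs(t_le - truth.latency_end_time_s) <= 1 / 30 + 1e-9


class TestComputeProfile:
    def test_triangle_curve_closed_form(self):
        """Linear rise 0->150 g.u. over 60 s then linear fall to 30 g.u. at 600 s."""
        fps = 30.0
        t = np.arange(0, 600 * 30 + 1) / fps
        y = np.where(t <= 60, 150.0 * t / 60.0, 150.0 - (t - 60) * (120.0 / 540.0))
        prof = compute_profile(make_trace(t, y), smoothing_window_s=0.0)
        assert prof.f_max_gu == pytest.approx(150.0, abs=1e-9)
        assert prof.t_max_s == pytest.approx(60.0, abs=1e-9)
        f160 = 150.0 - 100.0 * (120.0 / 540.0)
        assert prof.f100_gu == pytest.approx(f160, abs=1e-9)
        assert prof.fall100_gu == pytest.approx(150.0 - f160, abs=1e-9)
        # latency: baseline = mean of first 3 s of the ramp
        base = np.mean(y[t <= 3.0])
        expected_t_le = t[np.argmax(y >= base + 5.0)]
        assert prof.latency_end_time_s == pytest.approx(expected_t_le, abs=1e-9)

    def test_identity_suite_exact(self):
        for preset in GROUP_PRESETS.values():
            trace, _ = simulate_trace(preset, fps=10, duration_s=500, seed=3)
            prof = compute_profile(trace)
            for name, resid in prof.identity_residuals().items():
                assert abs(resid) <= 1e-9, name

    @pytest.mark.parametrize("group", list(GROUP_PRESETS))
    def test_noise_free_recovery(self, group):
        params = replace(GROUP_PRESETS[group], noise_sd_gu=0.0)
        fps = 10.0
        trace, truth = simulate_trace(params, fps=fps, duration_s=600)
        prof = compute_profile(trace)
        for f in TIME_FIELDS:
            assert abs(getattr(prof, f) - getattr(truth, f)) <= 1 / fps + 1e-9, f
        for f in INTENSITY_FIELDS:
            assert abs(getattr(prof, f) - getattr(truth, f)) <= 0.5, f

    def test_skew_kurtosis_match_brute_force(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 400.0, 0.5)
        y = np.clip(10 + 100 * np.exp(-((t - 100) ** 2) / 2000) + rng.normal(0, 2, t.size), 0, 255)
        y[:20] = 10.0  # quiet baseline so latency is detectable
        prof = compute_profile(make_trace(t, y))
        n = len(y)
        m = y.mean()
        m2 = np.sum((y - m) ** 2) / n
        m3 = np.sum((y - m) ** 3) / n
        m4 = np.sum((y - m) ** 4) / n
        g1 = m3 / m2**1.5
        skew_corr = g1 * np.sqrt(n * (n - 1)) / (n - 2)
        g2 = m4 / m2**2 - 3.0
        kurt_corr = ((n + 1) * g2 + 6) * (n - 1) / ((n - 2) * (n - 3))
        assert prof.skew == pytest.approx(skew_corr, abs=1e-9)
        assert prof.kurtosis == pytest.approx(kurt_corr, abs=1e-9)

    def test_short_trace_ends_before_t100_flagged_incomplete(self):
        params = replace(GROUP_PRESETS["control"], noise_sd_gu=0.0)
        trace, _ = simulate_trace(params, fps=10, duration_s=120)
        prof = compute_profile(trace)
        assert not prof.complete
        assert np.isnan(prof.f100_gu) and np.isnan(prof.fall100_gu)

    def test_trace_shorter_than_window_raises(self):
        t = np.arange(0.0, 0.2, 0.1)
        with pytest.raises(ValidationError):
            compute_profile(make_trace(t, [1.0, 2.0], fps=10), smoothing_window_s=1.0)

    def test_upslope_alternative_definition(self):
        params = replace(GROUP_PRESETS["control"], noise_sd_gu=0.0)
        trace, _ = simulate_trace(params, fps=10, duration_s=300)
        ratio = compute_profile(trace, upslope_from_latency=False)
        assert ratio.upslope_gradient_gu_per_s == pytest.approx(
            ratio.f_max_gu / ratio.t_max_s, abs=1e-9
        )

    def test_profiles_to_frame_columns(self):
        params = replace(GROUP_PRESETS["control"], noise_sd_gu=0.0)
        trace, _ = simulate_trace(params, fps=10, duration_s=300)
        df = profiles_to_frame([compute_profile(trace)])
        assert "f_max_gu" in df.columns and len(df) == 1


class TestLogFit:
    def test_exact_model_recovery(self):
        t = np.arange(0.0, 100.0)
        y = np.where(t < 5, 10.0, 20.0 * np.log(np.maximum(t - 5, 0) + 1.0) + 15.0)
        a, b, r2 = fit_log_curve(make_trace(t, y))
        assert a == pytest.approx(20.0, abs=1e-9)
        assert b == pytest.approx(15.0, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_post_latency_zero_variance_convention(self):
        t = np.arange(0.0, 50.0)
        y = np.where(t < 10, 0.0, 30.0)  # step then flat
        a, b, r2 = fit_log_curve(make_trace(t, y))
        assert a == pytest.approx(0.0, abs=1e-12)
        assert b == pytest.approx(30.0, abs=1e-12)
        assert r2 == 0.0

    def test_r2_matches_normal_equations_oracle(self):
        params = replace(GROUP_PRESETS["benign"], noise_sd_gu=0.0)
        trace, truth = simulate_trace(params, fps=5, duration_s=400)
        a, b, r2 = fit_log_curve(trace)
        t_le, _ = detect_latency_end(trace)
        t, y = trace.non_gap()
        sel = t >= t_le
        x = np.log(t[sel] - t_le + 1.0)
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y[sel])
        ss_res = np.sum((y[sel] - X @ beta) ** 2)
        ss_tot = np.sum((y[sel] - y[sel].mean()) ** 2)
        assert a == pytest.approx(beta[0], abs=1e-9)
        assert r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-9)


class TestGroupMeanCurves:
    def _trace(self, shift=0.0):
        params = replace(GROUP_PRESETS["control"], noise_sd_gu=0.0)
        t = np.arange(0, 3001) / 10.0
        from fluortrack.synth import curve_value

        return make_trace(t, np.asarray(curve_value(params, t)) + shift, fps=10)

    def test_mean_of_identical_traces_is_the_trace(self):
        tr = self._trace()
        _, mean = group_mean_curves({"tumour": [tr, tr]}, resample_fps=1.0)["tumour"]
        _, single = group_mean_curves({"tumour": [tr]}, resample_fps=1.0)["tumour"]
        assert np.allclose(mean, single, atol=1e-12)

    def test_linearity_of_the_mean(self):
        tr0, tr10 = self._trace(0.0), self._trace(10.0)
        base = group_mean_curves({"c": [tr0]}, resample_fps=1.0)["c"][1]
        mean = group_mean_curves({"c": [tr0, tr10]}, resample_fps=1.0)["c"][1]
        assert np.allclose(mean, base + 5.0, atol=1e-9)

    def test_empty_class_skipped_with_warning(self):
        tr = self._trace()
        with pytest.warns(UserWarning, match="no traces"):
            curves = group_mean_curves({"tumour": [tr], "control": []})
        assert "control" not in curves

    def test_monte_carlo_mean_near_analytic_expectation(self):
        params = GROUP_PRESETS["cancer"]  # noise_sd = 2
        traces = [
            simulate_trace(params, fps=5, duration_s=400, seed=s)[0] for s in range(5)
        ]
        curves = group_mean_curves({"tumour": traces}, resample_fps=1.0)
        grid, mean = curves["tumour"]
        from fluortrack.synth import curve_value, true_profile

        truth = true_profile(params, 5, 400)
        analytic = np.asarray(curve_value(params, grid + truth.latency_end_time_s))
        # MC error ~ sigma/sqrt(5) plus alignment error on the steep inflow
        assert np.mean(np.abs(mean - analytic)) < 2.0
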