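"""Oscillometric pipeline: separation, envelope, Gaussian fit, reverse lookup."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from healthgrid import oscillometry as osc
from healthgrid.oscillometry import (
    AmplitudeCoefficients,
    CuffDeflationRecording,
    EnvelopeTooSparseError,
    FitInvalidError,
    GaussianEnvelopeFit,
    PulseEnvelope,
    estimate_blood_pressure,
    estimate_pressures,
    extract_envelope,
    fit_envelope,
    separate_components,
    simulate_recording,
    solve_envelope_geometry,
)


def gaussian_envelope(x, y_max, x_max, s):
    return y_max * np.exp(-((np.asarray(x, dtype=float) - x_max) ** 2) / s)


def grid_search_sse(x, y, ymax_grid, xmax_grid, s_grid):
    """Brute-force minimum log-space SSE over a (y_max, x_max, s) grid."""
    z = np.log(y)
    best = np.inf
    for ym in ymax_grid:
        # broadcast (xmax, s, points)
        model = (
            math.log(ym)
            - (x[None, None, :] - xmax_grid[:, None, None]) ** 2 / s_grid[None, :, None]
        )
        sse = ((z[None, None, :] - model) ** 2).sum(axis=-1)
        best = min(best, float(sse.min()))
    return best


def make_envelope(x, y):
    pts = sorted(zip(map(float, x), map(float, y)), key=lambda p: -p[0])
    return PulseEnvelope(points=tuple(pts))


# ---------------------------------------------------------------------------
# Component separation
# ---------------------------------------------------------------------------

class TestSeparateComponents:
    fs = 100.0

    def _recording(self, pressure):
        t = np.arange(len(pressure)) / self.fs
        return CuffDeflationRecording(time=t, pressure=pressure, sample_rate=self.fs)

    def test_pure_ramp_has_no_dynamic_component(self):
        n = 4000
        ramp = np.linspace(170.0, 50.0, n)
        _, dynamic = separate_components(self._recording(ramp))
        assert np.abs(dynamic[200:-200]).max() < 0.01 * (170 - 50)

    def test_sinusoid_amplitude_recovered(self):
        n = 4000
        t = np.arange(n) / self.fs
        ramp = np.linspace(170.0, 50.0, n)
        injected = 1.5 * np.sin(2 * np.pi * 1.2 * t)
        _, dynamic = separate_components(self._recording(ramp + injected))
        recovered = np.abs(dynamic[500:-500]).max()
        assert recovered == pytest.approx(1.5, rel=0.05)

    def test_static_tracks_deflation_trend(self):
        rec = simulate_recording(120, 80, 72, seed=1)
        static, _ = separate_components(rec)
        interior = static[300:-300]
        assert np.all(np.diff(interior) <= 1e-6)

    def test_rejects_short_recording(self):
        t = np.arange(300) / self.fs
        rec = CuffDeflationRecording(
            time=t, pressure=np.full(300, 100.0), sample_rate=self.fs
        )
        with pytest.raises(ValueError, match="too short"):
            separate_components(rec)

    def test_rejects_undersampled_recording(self):
        fs = 10.0
        t = np.arange(100) / fs
        rec = CuffDeflationRecording(
            time=t, pressure=np.linspace(170, 50, 100), sample_rate=fs
        )
        with pytest.raises(ValueError, match="sample rate"):
            separate_components(rec)


# ---------------------------------------------------------------------------
# Envelope extraction
# ---------------------------------------------------------------------------

class TestExtractEnvelope:
    def test_pulse_count_matches_simulator_truth(self):
        rec = simulate_recording(120, 80, 72, seed=1)
        static, dynamic = separate_components(rec)
        env = extract_envelope(static, dynamic, rec.sample_rate)
        assert abs(len(env) - rec.truth.detectable_pulse_count()) <= 2

    def test_envelope_unimodal_after_smoothing(self):
        rec = simulate_recording(120, 80, 72, seed=2)
        static, dynamic = separate_components(rec)
        env = extract_envelope(static, dynamic, rec.sample_rate)
        smooth = np.convolve(env.y, np.ones(5) / 5, mode="valid")
        rises = np.sign(np.diff(smooth))
        changes = np.count_nonzero(np.diff(rises[rises != 0]))
        assert changes <= 1

    def test_all_amplitudes_positive(self):
        rec = simulate_recording(140, 90, 80, noise_sd=0.5, seed=3)
        static, dynamic = separate_components(rec)
        env = extract_envelope(static, dynamic, rec.sample_rate)
        assert np.all(env.y > 0)
        assert np.all(np.diff(env.x) < 0)  # deflation order

    def test_sparse_signal_rejected(self):
        # featureless noise with no pulse train
        rng = np.random.default_rng(0)
        n = 2000
        static = np.linspace(170, 50, n)
        dynamic = rng.normal(0, 1e-6, n)
        with pytest.raises(EnvelopeTooSparseError):
            extract_envelope(static, dynamic, 100.0)

    def test_envelope_type_enforces_positivity(self):
        with pytest.raises(ValueError, match="positive"):
            PulseEnvelope(points=((120.0, 1.0), (100.0, -0.5), (80.0, 1.0)))

    def test_envelope_type_enforces_minimum_points(self):
        with pytest.raises(EnvelopeTooSparseError):
            PulseEnvelope(points=((120.0, 1.0), (100.0, 2.0)))


# ---------------------------------------------------------------------------
# Log-linearized Gaussian fit
# ---------------------------------------------------------------------------

class TestFitEnvelope:
    def test_three_point_exact_solution(self):
        x = np.array([80.0, 100.0, 120.0])
        y = gaussian_envelope(x, 2.0, 100.0, 400.0)
        fit = fit_envelope(make_envelope(x, y))
        assert fit.y_max == pytest.approx(2.0, abs=1e-10)
        assert fit.x_max == pytest.approx(100.0, abs=1e-9)
        assert fit.s == pytest.approx(400.0, abs=1e-6)

    @pytest.mark.parametrize("y_max,x_max,s", [(2.0, 100.0, 400.0), (5.5, 87.0, 900.0)])
    def test_noiseless_recovery(self, y_max, x_max, s):
        x = np.linspace(x_max - 40, x_max + 40, 25)
        fit = fit_envelope(make_envelope(x, gaussian_envelope(x, y_max, x_max, s)))
        assert fit.y_max == pytest.approx(y_max, rel=1e-8)
        assert fit.x_max == pytest.approx(x_max, rel=1e-8)
        assert fit.s == pytest.approx(s, rel=1e-8)

    def test_noisy_fit_beats_grid_search_oracle(self):
        rng = np.random.default_rng(7)
        x = np.linspace(60.0, 140.0, 25)
        y = gaussian_envelope(x, 2.0, 100.0, 400.0) * np.exp(rng.normal(0, 0.05, 25))
        env = make_envelope(x, y)
        fit = fit_envelope(env)
        oracle = grid_search_sse(
            x, y,
            ymax_grid=np.arange(1.8, 2.2, 0.01),
            xmax_grid=np.arange(95.0, 105.0, 0.1),
            s_grid=np.arange(350.0, 450.0, 1.0),
        )
        assert fit.log_sse(env) <= oracle + 1e-12

    def test_back_mapping_is_exact_inverse(self):
        # points sampled from a returned fit reproduce the coefficients
        x = np.linspace(70, 130, 12)
        fit = fit_envelope(
            make_envelope(x, gaussian_envelope(x, 3.0, 95.0, 500.0))
        )
        refit = fit_envelope(make_envelope(x, fit.amplitude(x)))
        assert refit.b0 == pytest.approx(fit.b0, abs=1e-9)
        assert refit.b1 == pytest.approx(fit.b1, abs=1e-9)
        assert refit.b2 == pytest.approx(fit.b2, abs=1e-12)
        assert fit.s == pytest.approx(-1.0 / fit.b2)
        assert fit.x_max == pytest.approx(fit.b1 * fit.s / 2.0)

    def test_non_concave_log_envelope_rejected(self):
        # a valley instead of a peak
        with pytest.raises(FitInvalidError, match="concave"):
            fit_envelope(make_envelope([80, 100, 120], [1.0, 0.3, 1.0]))

    def test_collinear_abscissae_rejected(self):
        with pytest.raises(FitInvalidError):
            fit_envelope(make_envelope([100, 100, 100], [1.0, 1.1, 1.2]))

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=10, deadline=None)
    def test_fit_never_loses_to_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 31))
        x_max, s, y_max = 100.0, 400.0, 2.0
        x = np.sort(rng.uniform(60, 140, n))
        x += np.arange(n) * 1e-6  # ensure distinct
        y = gaussian_envelope(x, y_max, x_max, s) * np.exp(rng.normal(0, 0.1, n))
        env = make_envelope(x, y)
        try:
            fit = fit_envelope(env)
        except FitInvalidError:
            return  # degenerate draw: non-concave sample
        oracle = grid_search_sse(
            env.x, env.y,
            ymax_grid=np.arange(1.5, 2.5, 0.01),
            xmax_grid=np.arange(95.0, 105.0, 0.1),
            s_grid=np.arange(300.0, 500.0, 1.0),
        )
        assert fit.log_sse(env) <= oracle + 1e-12


# ---------------------------------------------------------------------------
# Reverse lookup
# ---------------------------------------------------------------------------

class TestEstimatePressures:
    fit = GaussianEnvelopeFit(
        y_max=2.0, x_max=100.0, s=400.0,
        b0=math.log(2.0) - 100.0**2 / 400.0, b1=2 * 100.0 / 400.0, b2=-1 / 400.0,
    )

    def test_closed_form_example(self):
        sp, dp = estimate_pressures(self.fit, AmplitudeCoefficients(0.48, 0.58))
        assert sp == pytest.approx(117.13, abs=0.005)
        assert dp == pytest.approx(85.24, abs=0.005)

    def test_equal_coefficients_are_symmetric(self):
        sp, dp = estimate_pressures(self.fit, AmplitudeCoefficients(0.5, 0.5))
        assert sp - self.fit.x_max == pytest.approx(self.fit.x_max - dp)

    def test_threshold_near_one_collapses_to_peak(self):
        sp, dp = estimate_pressures(
            self.fit, AmplitudeCoefficients(1 - 1e-9, 1 - 1e-9)
        )
        assert sp == pytest.approx(self.fit.x_max, abs=1e-2)
        assert dp == pytest.approx(self.fit.x_max, abs=1e-2)

    @given(ks=st.floats(0.46, 0.64), kd=st.floats(0.43, 0.73))
    @settings(max_examples=50, deadline=None)
    def test_ordering_over_admissible_coefficients(self, ks, kd):
        sp, dp = estimate_pressures(self.fit, AmplitudeCoefficients(ks, kd))
        assert dp < self.fit.x_max < sp

    def test_coefficients_validated(self):
        with pytest.raises(ValueError):
            AmplitudeCoefficients(ks=1.2, kd=0.5)


# ---------------------------------------------------------------------------
# Simulation and round trips
# ---------------------------------------------------------------------------

class TestSimulateRecording:
    def test_deterministic_for_fixed_seed(self):
        a = simulate_recording(120, 80, 72, noise_sd=1.0, seed=9)
        b = simulate_recording(120, 80, 72, noise_sd=1.0, seed=9)
        assert np.array_equal(a.pressure, b.pressure)
        assert np.array_equal(a.time, b.time)

    def test_rejects_bad_physiology(self):
        with pytest.raises(ValueError):
            simulate_recording(80, 120, 72)
        with pytest.raises(ValueError):
            simulate_recording(120, 80, 250)

    def test_geometry_solver_inverts_thresholds(self):
        x_max, s = solve_envelope_geometry(120.0, 80.0)
        assert x_max + math.sqrt(s * math.log(1 / 0.48)) == pytest.approx(120.0)
        assert x_max - math.sqrt(s * math.log(1 / 0.58)) == pytest.approx(80.0)

    @pytest.mark.parametrize("sp,dp", [(120, 80), (100, 70), (160, 95)])
    def test_noiseless_round_trip(self, sp, dp):
        rec = simulate_recording(sp, dp, 72, seed=1)
        estimate, _, _ = estimate_blood_pressure(rec)
        assert estimate.sp == pytest.approx(sp, abs=2.0)
        assert estimate.dp == pytest.approx(dp, abs=2.0)

    def test_explicit_width_round_trips_systolic(self):
        rec = simulate_recording(120, 80, 72, envelope_s=500.0, seed=4)
        estimate, fit, _ = estimate_blood_pressure(rec)
        assert estimate.sp == pytest.approx(120, abs=2.0)
        assert fit.s == pytest.approx(500.0, rel=0.1)

    def test_heart_rate_recovered(self):
        rec = simulate_recording(120, 80, 95, seed=6)
        estimate, _, _ = estimate_blood_pressure(rec)
        assert estimate.hr == pytest.approx(95, abs=3)

    def test_noisy_errors_moderate(self):
        errors = []
        for seed in range(10):
            rec = simulate_recording(120, 80, 72, noise_sd=1.0, seed=seed)
            estimate, _, _ = estimate_blood_pressure(rec)
            errors.append(abs(estimate.sp - 120))
        assert np.mean(errors) <= 5.0


class TestRecordingIO:
    def test_csv_round_trip(self, tmp_path):
        rec = simulate_recording(120, 80, 72, seed=1)
        path = tmp_path / "rec.csv"
        osc.write_recording_csv(rec, path)
        back = osc.read_recording_csv(path)
        assert back.sample_rate == pytest.approx(rec.sample_rate, rel=1e-6)
        np.testing.assert_allclose(back.pressure, rec.pressure, rtol=1e-9)

    def test_recording_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            CuffDeflationRecording(
                time=np.array([0.0, 0.0, 1.0]),
                pressure=np.array([100.0, 100.0, 100.0]),
                sample_rate=100.0,
            )
        with pytest.raises(ValueError, match="positive"):
            CuffDeflationRecording(
                time=np.array([0.0, 1.0]),
                pressure=np.array([100.0, -5.0]),
                sample_rate=100.0,
            )
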