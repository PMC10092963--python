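"""Autocorrelation, correlation time, geometry coefficient and aggregation."""

import math

import numpy as np
import pytest

from hepaflow import (
    AutocorrelationResult,
    OpticalGeometry,
    SpeckleTrace,
    aggregate_replicates,
    autocorrelation_fft,
    coefficient_k,
    correlation_time,
    velocity_from_tau,
)
from hepaflow.dls import estimate_velocity
from hepaflow.errors import CorrelationTimeNotReachedError, DegenerateTraceError
from hepaflow.synth import simulate_speckle


def direct_autocorrelation(x: np.ndarray, m: int) -> np.ndarray:
    """O(N^2) lag-sum oracle: biased, mean-subtracted, lag-0 normalized."""
    x = x - x.mean()
    n = len(x)
    r = np.array([np.dot(x[: n - k], x[k:]) for k in range(m)]) / n
    return r / r[0]


class TestAutocorrelation:
    def test_lag_zero_is_exactly_one(self, fast_speckle_scenario):
        traces, _ = simulate_speckle(fast_speckle_scenario)
        acf = autocorrelation_fft(traces[0])
        assert acf.g_normalized[0] == 1.0

    def test_matches_direct_lag_sum_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            x = rng.normal(size=2048)
            trace = SpeckleTrace(samples=x, sampling_rate=1e4)
            acf = autocorrelation_fft(trace)
            oracle = direct_autocorrelation(x, len(acf.g_normalized))
            assert np.max(np.abs(acf.g_normalized - oracle)) < 1e-10

    def test_bounded_by_one(self):
        rng = np.random.default_rng(1)
        trace = SpeckleTrace(samples=rng.normal(size=4096), sampling_rate=1e4)
        acf = autocorrelation_fft(trace)
        assert np.max(np.abs(acf.g_normalized)) <= 1.0 + 1e-9

    def test_constant_signal_raises_degenerate(self):
        trace = SpeckleTrace(samples=np.full(2048, 3.0), sampling_rate=1e4)
        with pytest.raises(DegenerateTraceError):
            autocorrelation_fft(trace)

    def test_too_short_record_rejected(self):
        trace = SpeckleTrace(samples=np.random.default_rng(0).normal(size=512),
                             sampling_rate=1e4)
        with pytest.raises(ValueError, match="1024"):
            autocorrelation_fft(trace)

    def test_estimated_acf_matches_gaussian_target(self, sim_geom):
        """Replicate-averaged ACF tracks exp(-(tau/tau_c)^2) within 0.05 RMS."""
        from hepaflow.synth import SpeckleScenario

        scen = SpeckleScenario(geometry=sim_geom, duration=0.2, snr=np.inf,
                               n_replicates=10, seed=21)
        traces, truth = simulate_speckle(scen)
        acfs = [autocorrelation_fft(t) for t in traces]
        lags = acfs[0].lags
        mean_g = np.mean([a.g_normalized for a in acfs], axis=0)
        mask = lags <= 2 * truth.tau_c
        target = np.exp(-((lags[mask] / truth.tau_c) ** 2))
        rms = float(np.sqrt(np.mean((mean_g[mask] - target) ** 2)))
        assert rms < 0.05


class TestCorrelationTime:
    @pytest.mark.parametrize("decay", ["gaussian", "exponential"])
    @pytest.mark.parametrize("tau_star", [3e-5, 2e-4, 1.7e-3])
    def test_exact_decay_read_at_one_over_e(self, decay, tau_star):
        """Both decays cross 1/e exactly at tau*, whatever the shape."""
        lags = np.linspace(0.0, 5 * tau_star, 2000)
        g = (
            np.exp(-((lags / tau_star) ** 2))
            if decay == "gaussian"
            else np.exp(-lags / tau_star)
        )
        acf = AutocorrelationResult(lags=lags, g_normalized=g)
        dt = lags[1] - lags[0]
        assert correlation_time(acf) == pytest.approx(tau_star, abs=dt)

    def test_interpolation_beats_nearest_sample_readout(self):
        """Linear interpolation at least halves the grid-quantization error."""
        rng = np.random.default_rng(5)
        err_interp, err_nearest = [], []
        for tau_star in rng.uniform(1e-4, 1e-3, size=100):
            lags = np.arange(0.0, 5e-3, 1e-4)
            g = np.exp(-((lags / tau_star) ** 2))
            acf = AutocorrelationResult(lags=lags, g_normalized=g)
            err_interp.append(abs(correlation_time(acf) - tau_star))
            k = int(np.flatnonzero(g < 1 / math.e)[0])
            nearest = lags[k] if abs(g[k] - 1 / math.e) < abs(g[k - 1] - 1 / math.e) else lags[k - 1]
            err_nearest.append(abs(nearest - tau_star))
        assert np.mean(err_interp) < 0.5 * np.mean(err_nearest)

    def test_never_reaching_level_raises(self):
        lags = np.linspace(0, 1e-4, 100)
        g = np.exp(-((lags / 1.0) ** 2))  # tau* far beyond the span
        acf = AutocorrelationResult(lags=lags, g_normalized=g)
        with pytest.raises(CorrelationTimeNotReachedError, match="record too short"):
            correlation_time(acf)

    def test_later_recrossings_ignored(self):
        lags = np.linspace(0, 1.0, 1000)
        g = np.exp(-((lags / 0.2) ** 2))
        g[600:] = 0.5  # artificial late bump back above 1/e
        acf = AutocorrelationResult(lags=lags, g_normalized=g)
        assert correlation_time(acf) == pytest.approx(0.2, abs=2e-3)


class TestGeometry:
    def test_hand_evaluated_coefficient(self, geom):
        # independent arithmetic: dx = lambda*l/(pi*omega) in mm, then
        # K = (omega^2 + sigma^2 dx^2)^(-1/2)
        lam_mm = 650.0e-6
        l_mm = 75.0
        dx = lam_mm * l_mm / (math.pi * 0.5)
        expected = (0.5**2 + 1.0**2 * dx**2) ** -0.5
        assert coefficient_k(geom) == pytest.approx(expected, rel=1e-12)
        assert geom.delta_x_mm == pytest.approx(dx, rel=1e-12)

    def test_negligible_speckle_term_limit_is_inverse_waist(self):
        geom = OpticalGeometry(wavelength_nm=650.0, distance_l_cm=1e-8,
                               beam_waist_mm=0.5, sigma=1.0)
        assert coefficient_k(geom) == pytest.approx(1.0 / 0.5, rel=1e-9)

    def test_monotone_decreasing_in_sigma_and_large_omega(self):
        base = dict(wavelength_nm=650.0, distance_l_cm=7.5)
        ks = [coefficient_k(OpticalGeometry(**base, beam_waist_mm=0.5, sigma=s))
              for s in np.linspace(1.0, 20.0, 10)]
        assert np.all(np.diff(ks) < 0)
        # beyond the turning point omega^2 = sigma*lambda*l/pi, K falls with omega
        turning = math.sqrt(650e-6 * 75.0 / math.pi)
        ks_omega = [coefficient_k(OpticalGeometry(**base, beam_waist_mm=w, sigma=1.0))
                    for w in np.linspace(1.5 * turning, 10 * turning, 10)]
        assert np.all(np.diff(ks_omega) < 0)

    def test_sigma_from_wavefront_curvature(self):
        geom = OpticalGeometry.from_rho(650.0, 7.5, 0.5, rho_cm=15.0)
        assert geom.sigma == pytest.approx(7.5 / 15.0 + 1.0)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            OpticalGeometry(sigma=0.5)
        with pytest.raises(ValueError):
            OpticalGeometry(beam_waist_mm=0.0)


class TestVelocity:
    def test_inverse_proportionality_in_tau(self, geom):
        v1 = velocity_from_tau(1e-3, geom)
        v2 = velocity_from_tau(2e-3, geom)
        assert v1 == pytest.approx(2.0 * v2, rel=1e-12)

    def test_algebraic_inverse_of_simulator_mapping(self, sim_geom):
        for v_star in (0.05, 0.7, 3.0):
            tau_c = 1.0 / (coefficient_k(sim_geom) * v_star)
            assert velocity_from_tau(tau_c, sim_geom) == pytest.approx(v_star, rel=1e-12)

    def test_nonpositive_tau_rejected(self, geom):
        with pytest.raises(ValueError):
            velocity_from_tau(0.0, geom)

    def test_velocity_invariant_under_amplitude_rescaling(self, fast_speckle_scenario):
        traces, _ = simulate_speckle(fast_speckle_scenario)
        tr = traces[0]
        v1, _ = estimate_velocity(tr, fast_speckle_scenario.geometry)
        scaled = SpeckleTrace(samples=tr.samples * 37.0, sampling_rate=tr.sampling_rate)
        v2, _ = estimate_velocity(scaled, fast_speckle_scenario.geometry)
        assert v2 == pytest.approx(v1, rel=1e-9)


class TestAggregation:
    def test_identical_replicates_have_zero_sd(self, fast_speckle_scenario):
        traces, _ = simulate_speckle(fast_speckle_scenario)
        v_single, _ = estimate_velocity(traces[0], fast_speckle_scenario.geometry)
        est = aggregate_replicates([traces[0]] * 10, fast_speckle_scenario.geometry)
        assert est.sd_velocity == pytest.approx(0.0, abs=1e-12)
        assert est.mean_velocity == pytest.approx(v_single, rel=1e-12)
        assert est.n_replicates == 10

    def test_degenerate_replicate_dropped_and_counted(self, fast_speckle_scenario):
        traces, _ = simulate_speckle(fast_speckle_scenario)
        flat = SpeckleTrace(samples=np.full(len(traces[0]), 5.0),
                            sampling_rate=traces[0].sampling_rate)
        est = aggregate_replicates([traces[0]] * 9 + [flat], fast_speckle_scenario.geometry)
        assert est.n_replicates == 9
        assert est.n_failed == 1
        assert "replicate 9" in est.failures[0]

    def test_all_replicates_failing_raises_with_causes(self, fast_speckle_scenario):
        flat = SpeckleTrace(samples=np.full(2048, 5.0), sampling_rate=1e4)
        with pytest.raises(CorrelationTimeNotReachedError, match="replicate 1"):
            aggregate_replicates([flat, flat], fast_speckle_scenario.geometry)

    def test_mismatched_sampling_rates_rejected(self):
        rng = np.random.default_rng(0)
        a = SpeckleTrace(samples=rng.normal(size=2048), sampling_rate=1e4)
        b = SpeckleTrace(samples=rng.normal(size=2048), sampling_rate=2e4)
        with pytest.raises(ValueError, match="sampling rate"):
            aggregate_replicates([a, b], OpticalGeometry())

    def test_sd_over_mean_shrinks_with_record_length(self, sim_geom):
        """Estimator variance falls as records lengthen (checked at 3 lengths)."""
        from hepaflow.synth import SpeckleScenario

        ratios = []
        for dur in (0.01, 0.04, 0.16):
            scen = SpeckleScenario(geometry=sim_geom, duration=dur, snr=np.inf,
                                   n_replicates=10, seed=9)
            traces, _ = simulate_speckle(scen)
            est = aggregate_replicates(traces, sim_geom)
            ratios.append(est.sd_velocity / est.mean_velocity)
        assert ratios[2] < ratios[1] < ratios[0]
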