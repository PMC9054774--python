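import numpy as np
import pytest

from windhover.errors import ValidationError
from windhover.flow import (
    SpectrumEstimate,
    VelocityTimeSeries,
    cone_filter,
    integral_length_scale,
    point_statistics,
    power_spectrum,
    spectral_slope,
)
from windhover.synthetic import TurbulenceSpec, generate_turbulence

from conftest import make_series


class TestConeFilter:
    def test_boundary_angles(self):
        # 44 deg off-axis retained, 46 deg rejected
        u = np.ones(4) * 6.0
        w = 6.0 * np.tan(np.radians([0.0, 44.0, 45.0, 46.0]))
        series = make_series(u, w=w)
        filtered, n_rejected = cone_filter(series, 45.0)
        assert n_rejected == 1
        assert len(filtered) == 3

    def test_all_within_cone(self, grid_b_series):
        _, n_rejected = cone_filter(grid_b_series, 45.0)
        assert n_rejected == 0

    def test_axial_flow_unchanged(self):
        series = make_series(np.full(100, 6.0))
        filtered, n_rejected = cone_filter(series, 45.0)
        assert n_rejected == 0
        assert filtered is series

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        series = make_series(
            6.0 + rng.standard_normal(500),
            v=3.0 * rng.standard_normal(500),
            w=3.0 * rng.standard_normal(500),
        )
        once, n1 = cone_filter(series, 45.0)
        twice, n2 = cone_filter(once, 45.0)
        assert n1 > 0
        assert n2 == 0
        assert np.array_equal(once.u, twice.u)

    def test_reversed_flow_rejected(self):
        series = make_series([6.0, -6.0, 6.0])
        _, n_rejected = cone_filter(series, 45.0)
        assert n_rejected == 1

    def test_invalid_half_angle(self):
        with pytest.raises(ValidationError):
            cone_filter(make_series([6.0, 6.0]), 0.0)

    def test_empty_series_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            make_series([])


class TestPointStatistics:
    def test_uniform_axial(self):
        stats = point_statistics(make_series(np.full(1000, 6.0)))
        assert stats.pitch_angle == 0.0
        assert stats.turbulence_intensity == 0.0
        assert stats.mean_speed == pytest.approx(6.0)

    def test_pitch_angle_definition(self):
        n = 1000
        series = make_series(np.full(n, 6.0), w=np.full(n, 6.0 * np.tan(np.radians(10.0))))
        assert point_statistics(series).pitch_angle == pytest.approx(10.0, abs=1e-9)

    def test_sinusoid_turbulence_intensity(self):
        # std of a sinusoid over whole periods = amplitude / sqrt(2)
        fs = 1000.0
        t = np.arange(int(fs * 4)) / fs  # 4 whole periods of 1 Hz
        series = make_series(6.0 + 0.6 * np.sqrt(2.0) * np.sin(2 * np.pi * t), sample_rate=fs)
        assert point_statistics(series).turbulence_intensity == pytest.approx(0.100, abs=1e-3)

    def test_lateral_sinusoid_does_not_change_ti(self):
        fs = 1000.0
        t = np.arange(int(fs * 2)) / fs
        u = np.full(len(t), 6.0)
        base = point_statistics(make_series(u, sample_rate=fs))
        wobble = point_statistics(
            make_series(u, v=1.5 * np.sin(2 * np.pi * 5 * t), sample_rate=fs)
        )
        assert wobble.turbulence_intensity == base.turbulence_intensity
        assert wobble.pitch_angle == base.pitch_angle

    def test_nonpositive_mean_u(self):
        with pytest.raises(ValidationError):
            point_statistics(make_series(np.full(10, -1.0)))

    def test_rejection_count_carried(self):
        stats = point_statistics(make_series(np.full(10, 6.0)), n_rejected=3)
        assert stats.n_rejected == 3
        assert stats.n_samples == 10


class TestPowerSpectrum:
    def test_sinusoid_parseval(self):
        fs, amp, f0 = 1250.0, 0.5, 10.0
        t = np.arange(int(fs * 60)) / fs
        series = make_series(6.0 + amp * np.sin(2 * np.pi * f0 * t), sample_rate=fs)
        spec = power_spectrum(series)
        total = np.trapezoid(spec.density, spec.frequency)
        assert total == pytest.approx(amp**2 / 2.0, rel=0.05)
        # spectral mass concentrated at f0
        peak = spec.frequency[np.argmax(spec.density)]
        assert peak == pytest.approx(f0, abs=0.5)

    def test_white_noise_flat_density(self):
        rng = np.random.default_rng(3)
        fs, sigma = 1250.0, 1.0
        series = make_series(6.0 + sigma * rng.standard_normal(int(fs * 60)), sample_rate=fs)
        spec = power_spectrum(series)
        expected = sigma**2 / (fs / 2.0)
        band = (spec.frequency > 10) & (spec.frequency < 600)
        assert np.mean(spec.density[band]) == pytest.approx(expected, rel=0.05)

    def test_parseval_on_turbulent_records(self):
        for seed in (0, 1, 2):
            series = generate_turbulence(TurbulenceSpec(6.0, 0.126, 0.31, seed=seed))
            spec = power_spectrum(series)
            total = np.trapezoid(spec.density, spec.frequency)
            assert total == pytest.approx(np.var(series.u), rel=0.05)

    def test_too_short_series(self):
        with pytest.raises(ValidationError):
            power_spectrum(make_series(np.full(100, 6.0)), segment_seconds=8.0)

    def test_frequencies_positive_ascending(self, grid_b_series):
        spec = power_spectrum(grid_b_series)
        assert spec.frequency[0] > 0
        assert np.all(np.diff(spec.frequency) > 0)


class TestSpectralSlope:
    def test_exact_power_law(self):
        f = np.linspace(1.0, 100.0, 200)
        spec = SpectrumEstimate(frequency=f, density=f**-2.0, segment_length=0)
        assert spectral_slope(spec, (2.0, 90.0)) == pytest.approx(-2.0, abs=1e-12)

    def test_white_noise_slope_zero(self):
        rng = np.random.default_rng(5)
        series = make_series(6.0 + rng.standard_normal(75000))
        spec = power_spectrum(series)
        assert spectral_slope(spec, (6.0, 600.0)) == pytest.approx(0.0, abs=0.1)

    def test_kolmogorov_slope_of_synthetic_turbulence(self, grid_b_series):
        spec = power_spectrum(grid_b_series)
        assert spectral_slope(spec, (6.0, 60.0)) == pytest.approx(-5.0 / 3.0, abs=0.15)

    def test_band_errors(self, grid_b_series):
        spec = power_spectrum(grid_b_series)
        with pytest.raises(ValidationError):
            spectral_slope(spec, (60.0, 6.0))
        with pytest.raises(ValidationError):
            spectral_slope(spec, (0.0, 60.0))  # below support
        with pytest.raises(ValidationError):
            spectral_slope(spec, (6.0, 6.2))  # fewer than 5 bins


class TestIntegralLengthScale:
    def test_exponential_autocorrelation_oracle(self):
        # AR(1) has exactly exponential autocorrelation with time constant
        # tau = -dt/ln(a); closed form: integral of exp(-s/tau) = tau, so
        # L = mean_u * tau.  The numerical-integration oracle confirms the
        # closed form before it is asserted against the estimator.
        fs, tau, mean_u = 250.0, 0.08, 6.0
        dt = 1.0 / fs
        a = np.exp(-dt / tau)
        rng = np.random.default_rng(11)
        n = int(fs * 600)
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.standard_normal(n) * np.sqrt(1 - a**2)
        for k in range(1, n):
            x[k] = a * x[k - 1] + eps[k]
        series = make_series(mean_u + x, sample_rate=fs)
        lags = np.arange(0, int(10 * tau * fs)) * dt
        oracle_timescale = np.trapezoid(np.exp(-lags / tau), dx=dt)
        assert oracle_timescale == pytest.approx(tau, rel=1e-3)
        assert integral_length_scale(series) == pytest.approx(mean_u * tau, rel=0.10)

    def test_white_noise_scale_tiny(self):
        rng = np.random.default_rng(1)
        series = make_series(6.0 + rng.standard_normal(75000))
        assert integral_length_scale(series) <= 0.01

    def test_recovers_generator_target_across_seeds(self):
        # distribution over >= 10 seeds, each within +-20 % of 0.31 m
        estimates = [
            integral_length_scale(
                generate_turbulence(TurbulenceSpec(6.0, 0.126, 0.31, seed=seed))
            )
            for seed in range(10)
        ]
        assert all(0.248 <= est <= 0.372 for est in estimates)

    def test_zero_variance_error(self):
        with pytest.raises(ValidationError):
            integral_length_scale(make_series(np.full(1000, 6.0)))


class TestVelocityTimeSeries:
    def test_mismatched_lengths(self):
        with pytest.raises(ValidationError):
            VelocityTimeSeries(
                t=[0.0, 0.1], u=[1.0], v=[0.0, 0.0], w=[0.0, 0.0], sample_rate=10.0
            )

    def test_nonmonotonic_time(self):
        with pytest.raises(ValidationError):
            VelocityTimeSeries(
                t=[0.0, 0.2, 0.1], u=[1.0] * 3, v=[0.0] * 3, w=[0.0] * 3, sample_rate=10.0
            )

    def test_nonfinite_values(self):
        with pytest.raises(ValidationError):
            make_series([6.0, np.nan, 6.0])
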