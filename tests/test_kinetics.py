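"""Transient and steady-state kinetics fitters."""

import numpy as np
import pytest

from motorcycle import (
    DwellTimeFitter,
    ExponentialTransientFitter,
    LinearRateFitter,
    OffRateCurveFitter,
    OffRateCurveParams,
    SaturationCurveFitter,
    Trace,
    fit_dwell_times,
    fit_exponential,
    fit_linear_kobs,
    fit_off_rate_vs_adp,
    fit_saturation,
    gen_dwell_table,
    gen_kobs_series,
    gen_stopped_flow_trace,
    half_site_amplitude_ratio,
    off_rate_at_adp,
)


class TestExponentialFits:
    def test_single_phase_noiseless_recovery(self):
        trace = gen_stopped_flow_trace(100.0, 1.0, 0.1, duration_s=0.06)
        fit = fit_exponential(trace, n_phases=1, t_start=0.002)
        assert fit.rates[0] == pytest.approx(100.0, rel=1e-6)
        assert fit.amplitudes[0] == pytest.approx(1.0, rel=1e-6)
        assert fit.offset == pytest.approx(0.1, abs=1e-8)

    def test_double_phase_noiseless_recovery(self):
        trace = gen_stopped_flow_trace(
            [300.0, 30.0], [0.5, 0.5], 0.2, duration_s=0.2, dt_s=2e-4
        )
        fit = fit_exponential(trace, n_phases=2, t_start=0.0)
        assert fit.rates[0] == pytest.approx(300.0, rel=0.01)  # fast first
        assert fit.rates[1] == pytest.approx(30.0, rel=0.01)
        assert fit.k_obs == pytest.approx(300.0, rel=0.01)

    def test_dead_time_truncation_unbiased(self):
        """Restricting an exponential to t >= 2 ms keeps the same rate."""
        trace = gen_stopped_flow_trace(354.0, -1.0, 1.0, duration_s=0.03)
        full = fit_exponential(trace, t_start=0.0)
        truncated = fit_exponential(trace, t_start=0.002)
        assert truncated.rates[0] == pytest.approx(354.0, rel=1e-6)
        assert truncated.rates[0] == pytest.approx(full.rates[0], rel=1e-6)

    def test_two_phase_fit_of_single_phase_data(self):
        """The spare phase gets negligible amplitude, not a split rate."""
        trace = gen_stopped_flow_trace(120.0, 1.0, 0.3, duration_s=0.06)
        fit = fit_exponential(trace, n_phases=2, t_start=0.0)
        amps = sorted(abs(a) for a in fit.amplitudes)
        assert amps[0] / sum(amps) < 0.01
        main_rate = fit.phases[np.argmax(np.abs(fit.amplitudes))][0]
        assert main_rate == pytest.approx(120.0, rel=1e-4)

    def test_flat_trace_flagged(self):
        trace = Trace(np.linspace(0, 0.1, 50), np.full(50, 0.7))
        fit = fit_exponential(trace)
        assert fit.flat
        assert fit.total_amplitude == 0.0
        assert fit.offset == pytest.approx(0.7)

    def test_rising_trace_negative_amplitude(self):
        trace = gen_stopped_flow_trace(50.0, -2.0, 2.0, duration_s=0.15)
        fit = fit_exponential(trace, t_start=0.0)
        assert fit.rates[0] == pytest.approx(50.0, rel=1e-6)
        assert fit.amplitudes[0] == pytest.approx(-2.0, rel=1e-6)

    def test_predict_round_trip(self):
        trace = gen_stopped_flow_trace(80.0, 1.0, 0.0, duration_s=0.08)
        fitter = ExponentialTransientFitter().fit(trace)
        assert np.allclose(fitter.predict(trace.time_s), trace.signal,
                           atol=1e-8)


class TestLinearRateFits:
    def test_exchange_series_recovered_exactly(self):
        concs = [2.5, 5.0, 7.5, 10.0]
        out = fit_linear_kobs(concs, [29.0 * c + 354.0 for c in concs])
        assert out["slope"] == pytest.approx(29.0)
        assert out["intercept"] == pytest.approx(354.0)

    def test_microtubule_on_rate_series(self):
        concs = [0.25, 0.5, 1.0, 2.0]
        out = fit_linear_kobs(concs, [17.0 * c for c in concs])
        assert out["slope"] == pytest.approx(17.0)
        assert out["intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_two_points_interpolate(self):
        out = fit_linear_kobs([1.0, 3.0], [5.0, 9.0])
        assert out["slope"] == pytest.approx(2.0)
        assert out["intercept"] == pytest.approx(3.0)

    def test_single_concentration_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_kobs([2.0, 2.0], [1.0, 1.1])


class TestSaturationFits:
    concs = [10, 25, 50, 100, 250, 500, 1000]

    def test_half_site_parameters_recovered(self):
        series = gen_kobs_series("saturation", (172.0, 119.0), self.concs)
        fit = fit_saturation(series["conc_um"], series["kobs_per_s"])
        assert fit.kmax == pytest.approx(172.0, rel=1e-6)
        assert fit.k_half == pytest.approx(119.0, rel=1e-6)

    def test_rate_at_k_half_is_midpoint(self):
        fitter = SaturationCurveFitter(with_baseline=True)
        series = gen_kobs_series("saturation", (10.0, 50.0, 2.0),
                                 [5, 20, 50, 150, 400])
        fitter.fit(series["conc_um"], series["kobs_per_s"])
        mid = fitter.predict([fitter.k_half_])[0]
        assert mid == pytest.approx((fitter.kmax_ + fitter.baseline_) / 2,
                                    rel=1e-6)

    def test_equal_weights_match_unweighted(self):
        series = gen_kobs_series("saturation", (115.0, 1.2),
                                 [0.25, 0.5, 1, 2, 5, 10], noise_sd=3.0,
                                 seed=3)
        fit_eq = fit_saturation(series["conc_um"], series["kobs_per_s"],
                                weights=np.full(6, 2.0))
        fit_un = fit_saturation(series["conc_um"], series["kobs_per_s"])
        assert fit_eq.kmax == pytest.approx(fit_un.kmax, rel=1e-9)
        assert fit_eq.k_half == pytest.approx(fit_un.k_half, rel=1e-9)

    def test_scale_equivariance(self):
        series = gen_kobs_series("saturation", (172.0, 119.0), self.concs)
        base = fit_saturation(series["conc_um"], series["kobs_per_s"])
        scaled = fit_saturation(series["conc_um"],
                                3.0 * series["kobs_per_s"])
        assert scaled.kmax == pytest.approx(3.0 * base.kmax, rel=1e-6)
        assert scaled.k_half == pytest.approx(base.k_half, rel=1e-6)

    def test_extrapolated_k_half_flagged(self):
        series = gen_kobs_series("saturation", (100.0, 500.0), [1, 2, 5, 10])
        with pytest.warns(UserWarning, match="extrapolation"):
            fit = fit_saturation(series["conc_um"], series["kobs_per_s"])
        assert fit.extrapolated

    def test_too_few_concentrations(self):
        with pytest.raises(ValueError):
            fit_saturation([1, 2], [5, 8])


class TestDwellTimes:
    def test_continuous_sample_recovery(self):
        dwells = gen_dwell_table(0.2, 500, frame_interval_s=0.0, seed=4)
        out = fit_dwell_times(dwells)
        assert out["mean_dwell_s"] == pytest.approx(5.0, rel=0.10)

    def test_frame_quantized_sample_recovery(self):
        """5-fps quantization and 2-frame detection limit stay within 5%."""
        dwells = gen_dwell_table(1 / 3.7, 2000, frame_interval_s=0.2, seed=5)
        out = fit_dwell_times(dwells)
        assert out["mean_dwell_s"] == pytest.approx(3.7, rel=0.05)
        assert out["koff_per_s"] == pytest.approx(0.27, abs=0.015)

    def test_ideal_sample_inverts_to_off_rate(self):
        """koff = 1/mean dwell: 3.7 s -> 0.27 /s (2 d.p.)."""
        # deterministic 'ideal' exponential sample via quantile midpoints
        q = (np.arange(2000) + 0.5) / 2000
        dwells = -3.7 * np.log1p(-q)
        out = fit_dwell_times(dwells)
        assert round(out["koff_per_s"], 2) == 0.27
        # apo condition: 10.6 s dwell -> 0.09 /s
        out_apo = fit_dwell_times(-10.6 * np.log1p(-q))
        assert round(out_apo["koff_per_s"], 2) == 0.09

    def test_unbiased_within_monte_carlo_error(self):
        """Fitted off-rate matches the generating rate within 3 SE."""
        koffs = [
            DwellTimeFitter().fit(
                gen_dwell_table(0.27, 500, seed=s)).koff_
            for s in range(200)
        ]
        se_mean = np.std(koffs) / np.sqrt(len(koffs))
        assert abs(np.mean(koffs) - 0.27) < 3 * se_mean

    def test_too_few_dwells(self):
        with pytest.raises(ValueError):
            fit_dwell_times([1.0] * 5)


class TestOffRateCurveFits:
    truth = OffRateCurveParams(0.09, 0.27, 93.0)

    def test_noiseless_exact_recovery(self):
        concs = [0, 10, 100, 300, 1000, 3000]
        koffs = [off_rate_at_adp(self.truth, c) for c in concs]
        params = fit_off_rate_vs_adp(concs, koffs)
        assert params.koff_apo == pytest.approx(0.09, rel=1e-4)
        assert params.koff_max == pytest.approx(0.27, rel=1e-4)
        assert params.k_d == pytest.approx(93.0, rel=1e-3)

    def test_zero_concentration_pins_apo_rate(self):
        concs = [0, 50, 200, 800]
        koffs = [off_rate_at_adp(self.truth, c) for c in concs]
        params = fit_off_rate_vs_adp(concs, koffs)
        assert params.koff_apo == pytest.approx(0.09, rel=1e-3)

    def test_sparse_measured_points_converge_with_wide_kd_ci(self):
        """Four printed measurements: the K_D is poorly conditioned."""
        fitter = OffRateCurveFitter().fit(
            [0, 10, 300, 1000], [0.09, 0.14, 0.21, 0.27]
        )
        lo, hi = fitter.ci95_["k_d"]
        assert hi - lo > 100.0
        assert 0 < fitter.params_.koff_max < 1.0


class TestHalfSiteAmplitudes:
    @staticmethod
    def _fit(amplitude):
        trace = gen_stopped_flow_trace(150.0, amplitude, 0.0,
                                       duration_s=0.05)
        return fit_exponential(trace, t_start=0.0)

    def test_identical_traces_ratio_one(self):
        fit = self._fit(0.36)
        assert half_site_amplitude_ratio(fit, fit) == pytest.approx(1.0)

    def test_one_vs_two_adp_release(self):
        # no-nucleotide control releases one of the two bound ADPs
        assert half_site_amplitude_ratio(
            self._fit(0.5), self._fit(1.0)
        ) == pytest.approx(0.5, rel=1e-6)

    def test_measured_amplitude_ratio(self):
        # amplitudes 0.2 (no nucleotide) vs 0.36 (saturating ATP)
        ratio = half_site_amplitude_ratio(self._fit(0.2), self._fit(0.36))
        assert ratio == pytest.approx(0.2 / 0.36, rel=1e-6)
        assert round(ratio, 2) == 0.56

    def test_zero_reference_rejected(self):
        flat = fit_exponential(
            Trace(np.linspace(0, 0.1, 30), np.zeros(30)))
        with pytest.raises(ZeroDivisionError):
            half_site_amplitude_ratio(self._fit(1.0), flat)
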