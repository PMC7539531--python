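import math

import numpy as np
import pytest

from piezokit import (
    BoltzmannFitError,
    CurrentTrace,
    PressureResponse,
    StimulusEpoch,
    amplitude_histogram,
    boltzmann_fit,
    decay_rate,
    end_over_peak,
    peak_current,
    pressure_response,
    time_to_fraction_decay,
    unitary_conductance,
)

from conftest import step_trace


class TestPeak:
    def test_instant_step_peak_and_time(self):
        tr = step_trace(amplitude=-100.0)
        kin = peak_current(tr, "pulse")
        assert kin.peak_amplitude == pytest.approx(-100.0)
        assert kin.time_to_peak == pytest.approx(0.0, abs=1e-9)
        assert not kin.low_signal

    def test_linear_rise_time_to_peak(self):
        fs = 20_000.0
        n_base, n_rise, n_hold = 1000, 300, 1000
        rise = np.linspace(0, -50.0, n_rise + 1)[1:]
        current = np.concatenate([np.zeros(n_base), rise, np.full(n_hold, -50.0)])
        onset = n_base / fs
        tr = CurrentTrace(current, fs, [StimulusEpoch(onset, onset + (n_rise + n_hold) / fs)])
        kin = peak_current(tr, "pulse")
        assert kin.time_to_peak == pytest.approx(15.0, abs=0.1)
        assert kin.peak_amplitude == pytest.approx(-50.0)

    def test_all_zero_trace_flagged_low_signal(self):
        fs = 20_000.0
        tr = CurrentTrace(np.zeros(4000), fs, [StimulusEpoch(0.05, 0.15)])
        kin = peak_current(tr, "pulse")
        assert kin.peak_amplitude == 0.0
        assert kin.time_to_peak == 0.0
        assert kin.low_signal

    def test_short_epoch_rejected(self):
        tr = CurrentTrace(np.zeros(2000), 20_000.0,
                          [StimulusEpoch(0.05, 0.05004)])
        with pytest.raises(ValueError):
            peak_current(tr, "pulse")


class TestFractionDecay:
    @pytest.mark.parametrize("k", [5.0, 10.0, 20.0, 50.0])
    def test_exponential_closed_form_within_one_sample(self, k):
        tr = step_trace(amplitude=-80.0, rate=k)
        t20, censored = time_to_fraction_decay(tr, "pulse", 0.2)
        assert not censored
        expected_ms = math.log(1.25) / k * 1e3
        assert abs(t20 - expected_ms) <= 1e3 / tr.sampling_rate

    def test_plateau_censored(self):
        tr = step_trace(amplitude=-80.0)  # no decay
        t20, censored = time_to_fraction_decay(tr, "pulse", 0.2)
        assert censored and t20 is None

    def test_residual_above_threshold_censored(self):
        tr = step_trace(amplitude=-80.0, rate=30.0, residual=0.85)
        t20, censored = time_to_fraction_decay(tr, "pulse", 0.2)
        assert censored and t20 is None

    def test_invalid_fraction(self):
        tr = step_trace()
        with pytest.raises(ValueError):
            time_to_fraction_decay(tr, "pulse", 1.5)


class TestDecayRate:
    def test_pure_exponential_rate_recovered(self):
        tr = step_trace(amplitude=-80.0, rate=20.0)
        res = decay_rate(tr, "pulse")
        assert not res.non_decaying
        assert res.rate == pytest.approx(20.0, abs=0.5)

    def test_flat_plateau_flagged_non_decaying(self):
        tr = step_trace(amplitude=-80.0)
        res = decay_rate(tr, "pulse")
        assert res.non_decaying
        assert res.rate is None

    def test_decay_with_offset_recovers_rate_and_offset(self):
        # deviation -20 - 60*exp(-12 t) pA: residual plateau 20 pA of 80 peak
        tr = step_trace(amplitude=-80.0, rate=12.0, residual=0.25)
        res = decay_rate(tr, "pulse")
        assert res.rate == pytest.approx(12.0, abs=0.5)
        assert res.offset == pytest.approx(20.0, abs=0.5)


class TestEndOverPeak:
    def test_plateau_at_peak_is_one(self):
        tr = step_trace(amplitude=-100.0)
        val = end_over_peak(tr, "pulse", (0.23, 0.25))
        assert val == pytest.approx(1.0)

    def test_full_inactivation_is_zero(self):
        tr = step_trace(amplitude=-100.0, rate=100.0)
        val = end_over_peak(tr, "pulse", (0.23, 0.25))
        assert val == pytest.approx(0.0, abs=1e-3)

    def test_forty_percent_residual(self):
        tr = step_trace(amplitude=-100.0, rate=80.0, residual=0.40)
        val = end_over_peak(tr, "pulse", (0.23, 0.25))
        assert val == pytest.approx(0.40, abs=0.01)

    def test_window_outside_epoch_rejected(self):
        tr = step_trace()
        with pytest.raises(ValueError):
            end_over_peak(tr, "pulse", (0.26, 0.30))


class TestAmplitudeHistogram:
    def test_bin_edges_are_multiples_of_bin_width(self):
        rng = np.random.default_rng(0)
        values = rng.normal(-1.0, 0.3, size=5000)
        hist = amplitude_histogram(values)
        ratio = hist.bin_edges / 0.05
        np.testing.assert_allclose(ratio, np.round(ratio), atol=1e-9)
        assert np.any(np.isclose(hist.bin_edges, round(hist.bin_edges[0] / 0.05) * 0.05))

    def test_boundary_value_falls_in_left_closed_bin(self):
        values = np.concatenate([np.full(2000, -1.95), np.full(2000, 0.0)])
        hist = amplitude_histogram(values + np.random.default_rng(1).normal(0, 0.01, 4000))
        edges = hist.bin_edges
        i = int(np.searchsorted(edges, -1.95, side="right")) - 1
        assert edges[i] == pytest.approx(-1.95)

    def test_constant_trace_single_level(self):
        hist = amplitude_histogram(np.full(2000, -3.0))
        assert hist.levels == (-3.0,)
        assert hist.unitary_amplitude is None

    def test_unimodal_distribution_single_level(self):
        rng = np.random.default_rng(2)
        hist = amplitude_histogram(rng.normal(-1.0, 0.1, size=8000))
        assert hist.unitary_amplitude is None
        assert hist.levels[0] == pytest.approx(-1.0, abs=0.02)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            amplitude_histogram(np.zeros(500))


class TestUnitaryConductance:
    @pytest.mark.parametrize("amp,holding,expected", [
        (1.95, -80.0, 24.375),
        (0.0, -80.0, 0.0),
        (2.0, -100.0, 20.0),
    ])
    def test_quotient(self, amp, holding, expected):
        assert unitary_conductance(amp, holding) == pytest.approx(expected)

    def test_zero_holding(self):
        with pytest.raises(ValueError):
            unitary_conductance(1.95, 0.0)


class TestPressureResponse:
    def test_normalization_to_anchor(self):
        pr = pressure_response(
            {-5: -10.0, -10: -50.0, -20: -100.0, -40: -200.0})
        by_p = dict(zip(pr.pressures.tolist(), pr.normalized_current.tolist()))
        assert by_p[-40.0] == pytest.approx(1.0)
        assert by_p[-20.0] == pytest.approx(0.5)

    def test_all_equal_amplitudes(self):
        pr = pressure_response({-5: -50.0, -10: -50.0, -20: -50.0, -40: -50.0})
        assert np.allclose(pr.normalized_current, 1.0)

    def test_missing_anchor_rejected(self):
        with pytest.raises(ValueError):
            pressure_response({-5: -1.0, -10: -2.0, -20: -3.0, -30: -4.0})


class TestBoltzmann:
    def test_noise_free_exact_recovery(self):
        p = np.array([-5.0, -10.0, -15.0, -20.0, -25.0, -30.0, -35.0, -40.0])
        y = 1.0 / (1.0 + np.exp((20.0 - np.abs(p)) / 5.0))
        pr = PressureResponse(pressures=p, normalized_current=y,
                              anchor_pressure=-40.0)
        fit = boltzmann_fit(pr)
        assert fit.P_half == pytest.approx(20.0, abs=1e-6)
        assert fit.slope == pytest.approx(5.0, abs=1e-6)
        assert fit.fit_residual < 1e-8

    def test_noisy_recovery_unbiased(self):
        rng = np.random.default_rng(11)
        p = -np.arange(5.0, 41.0, 5.0)
        ph, sl = [], []
        for _ in range(100):
            y = 1.0 / (1.0 + np.exp((20.0 - np.abs(p)) / 5.0))
            y = y + rng.normal(0, 0.05, y.size)
            fit = boltzmann_fit(PressureResponse(
                pressures=p, normalized_current=y, anchor_pressure=-40.0))
            ph.append(fit.P_half)
            sl.append(fit.slope)
        assert np.mean(ph) == pytest.approx(20.0, rel=0.05)
        assert np.mean(sl) == pytest.approx(5.0, rel=0.05)

    def test_saturated_points_flagged(self):
        p = np.array([-10.0, -20.0, -30.0, -40.0])
        y = np.array([0.98, 0.99, 1.0, 1.0])
        with pytest.raises(BoltzmannFitError) as exc:
            boltzmann_fit(PressureResponse(pressures=p, normalized_current=y,
                                           anchor_pressure=-40.0))
        assert exc.value.residuals is not None
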