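"""Pressure-trace I/O, peak detection, decay fitting and keff."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from blebmetrics import (DecayFit, InjectionProtocol, PressureSimSpec,
                         PressureTrace, cessation_time,
                         effective_decay_constant, fit_decay,
                         generate_pressure_trace, max_pressure, read_trace,
                         write_trace)
from blebmetrics.errors import AnalysisError, TraceFormatError
from blebmetrics.units import PSI_TO_KPA


def make_trace(p, rate=10.0, **markers):
    t = np.arange(len(p)) / rate
    return PressureTrace(t, np.asarray(p, float), rate, **markers)


class TestIO:
    def test_round_trip_lossless(self, tmp_path, noiseless_sim):
        trace = generate_pressure_trace(noiseless_sim)
        path = tmp_path / "trace.csv"
        write_trace(trace, path)
        back = read_trace(path)
        np.testing.assert_allclose(back.time_s, trace.time_s, atol=1e-9)
        np.testing.assert_allclose(back.pressure_kpa, trace.pressure_kpa,
                                   atol=1e-9)
        assert back.t_cess_s == trace.t_cess_s

    def test_duplicated_timestamp_names_the_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"time_s": [0.0, 0.1, 0.1, 0.3],
                      "pressure_kpa": [1, 2, 3, 4]}).to_csv(path, index=False)
        with pytest.raises(TraceFormatError) as err:
            read_trace(path)
        assert err.value.row == 2

    def test_nan_pressure_names_the_row(self, tmp_path):
        path = tmp_path / "nan.csv"
        pd.DataFrame({"time_s": [0.0, 0.1, 0.2],
                      "pressure_kpa": [1.0, np.nan, 2.0]}).to_csv(
            path, index=False)
        with pytest.raises(TraceFormatError) as err:
            read_trace(path)
        assert err.value.row == 1

    def test_psi_units_converted_on_read(self, tmp_path):
        path = tmp_path / "psi.csv"
        pd.DataFrame({"time_s": np.arange(5) / 10.0,
                      "pressure_psi": [1.0] * 5}).to_csv(path, index=False)
        back = read_trace(path)
        np.testing.assert_allclose(back.pressure_kpa, PSI_TO_KPA)


class TestCessation:
    def test_printed_protocol_durations(self):
        assert cessation_time(InjectionProtocol(4.5, 10.0)) == 27.0
        assert cessation_time(InjectionProtocol(9.0, 10.0)) == 54.0

    def test_vanishing_volume_limit(self):
        assert cessation_time(InjectionProtocol(1e-4, 10.0), 5.0) == \
            pytest.approx(5.0, abs=1e-3)


class TestMaxPressure:
    def test_spike_inside_window_detected(self):
        p = np.ones(400)
        p[260] = 9.0  # 26.0 s: 1 s before cessation at 27 s
        value, t = max_pressure(make_trace(p), 27.0)
        assert (value, t) == (9.0, 26.0)

    def test_spike_outside_window_ignored(self):
        p = np.ones(400)
        p[300] = 9.0  # 30 s: 3 s after cessation
        value, _ = max_pressure(make_trace(p), 27.0)
        assert value == 1.0

    def test_constant_trace_ties_break_earliest(self):
        value, t = max_pressure(make_trace(np.ones(400)), 27.0, window_s=2.0)
        assert value == 1.0 and t == 25.0

    def test_window_beyond_recording_fails(self):
        with pytest.raises(AnalysisError):
            max_pressure(make_trace(np.ones(100)), 27.0)


class TestFitDecay:
    def test_noiseless_parameters_recovered_to_0p1pct(self, noiseless_sim):
        trace = generate_pressure_trace(noiseless_sim)
        fit = fit_decay(trace, trace.t_cess_s)
        for got, want in [(fit.A1_kpa, 10.0), (fit.k1_per_s, 0.5),
                          (fit.A2_kpa, 5.0), (fit.k2_per_s, 0.05)]:
            assert got == pytest.approx(want, rel=1e-3)
        assert fit.converged

    def test_single_exponential_degenerates_gracefully(self, protocol_4p5):
        spec = PressureSimSpec(protocol=protocol_4p5, baseline_kpa=0.0,
                               A1_kpa=10.0, A2_kpa=0.0, k1_per_s=0.3,
                               k2_per_s=0.01, noise_sd=0.0, duration_s=180.0)
        trace = generate_pressure_trace(spec)
        fit = fit_decay(trace, trace.t_cess_s)
        assert effective_decay_constant(fit) == pytest.approx(0.3, rel=0.01)

    def test_flat_trace_flagged_non_identifiable(self):
        trace = make_trace(np.full(2000, 3.0), t_cess_s=27.0)
        try:
            fit = fit_decay(trace, 27.0)
        except AnalysisError:
            return  # explicit failure is also acceptable for a flat trace
        assert fit.A1_kpa + fit.A2_kpa == pytest.approx(0.0, abs=1e-6)
        assert not fit.identifiable

    def test_baseline_shift_invariance(self, noiseless_sim, protocol_4p5):
        shifted_spec = PressureSimSpec(
            protocol=protocol_4p5, baseline_kpa=7.5, A1_kpa=10.0, A2_kpa=5.0,
            k1_per_s=0.5, k2_per_s=0.05, noise_sd=0.0, duration_s=180.0)
        f0 = fit_decay(generate_pressure_trace(noiseless_sim), 27.0)
        f1 = fit_decay(generate_pressure_trace(shifted_spec), 27.0)
        assert f1.k1_per_s == pytest.approx(f0.k1_per_s, rel=1e-3)
        assert f1.k2_per_s == pytest.approx(f0.k2_per_s, rel=1e-3)
        assert f1.baseline_kpa == pytest.approx(7.5, abs=0.01)

    def test_too_few_samples_fails(self, noiseless_sim):
        trace = generate_pressure_trace(noiseless_sim)
        short = PressureTrace(trace.time_s[:300], trace.pressure_kpa[:300],
                              trace.rate_hz)
        with pytest.raises(AnalysisError):
            fit_decay(short, 27.0)  # only ~3 s after the peak


class TestKeff:
    def test_equal_amplitudes_give_mean_rate(self):
        fit = DecayFit(2.0, 2.0, 0.4, 0.1, 0.25, 0.0, 0.0, True)
        assert effective_decay_constant(fit) == pytest.approx(0.25)

    def test_single_component_gives_k1(self):
        fit = DecayFit(3.0, 0.0, 0.4, 0.1, 0.4, 0.0, 0.0, True)
        assert effective_decay_constant(fit) == pytest.approx(0.4)

    def test_direct_substitution(self):
        # (2*0.3 + 1*0.03) / 3 = 0.21
        fit = DecayFit(2.0, 1.0, 0.3, 0.03, 0.21, 0.0, 0.0, True)
        assert effective_decay_constant(fit) == pytest.approx(0.21)

    def test_zero_total_amplitude_fails(self):
        fit = DecayFit(0.0, 0.0, 0.4, 0.1, np.nan, 0.0, 0.0, True)
        with pytest.raises(AnalysisError):
            effective_decay_constant(fit)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(a1=st.floats(0.0, 100.0), a2=st.floats(0.0, 100.0),
           k1=st.floats(1e-3, 10.0), k2=st.floats(1e-3, 10.0))
    def test_keff_bounded_by_rate_constants(self, a1, a2, k1, k2):
        if a1 + a2 == 0:
            return
        k1, k2 = max(k1, k2), min(k1, k2)
        fit = DecayFit(a1, a2, k1, k2, np.nan, 0.0, 0.0, True)
        keff = effective_decay_constant(fit)
        assert k2 - 1e-12 <= keff <= k1 + 1e-12


class TestNoisyRecovery:
    def test_median_parameter_recovery_over_100_seeded_traces(
            self, protocol_4p5):
        """2%-of-peak Gaussian noise, 10 Hz, 120 s window: median relative
        error of keff stays within 5% and of A1+A2 within 2%."""
        keff_err, amp_err = [], []
        for seed in range(100):
            spec = PressureSimSpec(
                protocol=protocol_4p5, A1_kpa=10.0, A2_kpa=5.0,
                k1_per_s=0.5, k2_per_s=0.05, noise_sd=0.02 * 15.0,
                rate_hz=10.0, duration_s=180.0, seed=seed)
            fit = fit_decay(generate_pressure_trace(spec), 27.0)
            keff_err.append(abs(fit.keff_per_s - 0.35) / 0.35)
            amp_err.append(abs(fit.A1_kpa + fit.A2_kpa - 15.0) / 15.0)
        assert np.median(keff_err) <= 0.05
        assert np.median(amp_err) <= 0.02
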