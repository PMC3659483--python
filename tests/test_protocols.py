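"""Tests for stimulus construction, simulation and feature extraction."""

import numpy as np
import pytest

import ionfit
from ionfit.model import CellState, ModelParameters, gate_equilibrium
from ionfit.protocols import (
    StimulusProtocol,
    Trace,
    extract_features,
    phase_plot,
    rms_error,
    simulate,
    stimulus_value,
)


class TestStimulus:
    def test_spontaneous_is_zero(self):
        proto = StimulusProtocol.spontaneous()
        assert stimulus_value(proto, 0.123) == 0.0

    def test_pulse_amplitude_and_sign(self):
        # 30 uA/cm^2, 2 ms pulses every 400 ms: inside a pulse the applied
        # current is -30000 nA/cm^2 (inward, depolarising)
        proto = StimulusProtocol.uniform(0.4, 5, amplitude=30.0, pulse_width=2e-3)
        assert stimulus_value(proto, 0.4005) == -30000.0
        assert stimulus_value(proto, 0.3999) == 0.0

    def test_window_is_half_open(self):
        proto = StimulusProtocol.uniform(0.4, 5, amplitude=30.0, pulse_width=2e-3)
        assert stimulus_value(proto, 0.4) == -30000.0
        assert stimulus_value(proto, 0.402) == 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            StimulusProtocol("uniform", 30.0, 0.0, np.array([0.1]))
        with pytest.raises(ValueError):
            StimulusProtocol.sequence([0.2, 0.1], 30.0)

    def test_round_trip(self):
        proto = StimulusProtocol.sequence([0.1, 0.25, 0.5], 13.0)
        again = StimulusProtocol.from_dict(proto.to_dict())
        np.testing.assert_allclose(again.onsets, proto.onsets)
        assert again.amplitude == proto.amplitude


class TestSimulate:
    def test_leak_only_relaxes_to_reversal(self):
        params = ModelParameters((), gL=2.0, ErevL=-60.0, Cm=1.0)
        x0 = CellState(0.0, np.empty(0))
        tr = simulate(params, x0, StimulusProtocol.spontaneous(), 2.0, 1e-3)
        # RC decay: Em(t) = ErevL + (Em0 - ErevL) exp(-gL t / Cm), tau = 0.5 s
        expected = -60.0 + 60.0 * np.exp(-2.0 * tr.t)
        np.testing.assert_allclose(tr.Em, expected, atol=1e-4)
        assert np.all(np.diff(tr.Em) <= 1e-12)

    def test_voltage_clamp_matches_closed_form(self, csan):
        """With an effectively infinite membrane capacitance Em is frozen
        and each gate must follow g_inf + (g0 - g_inf) exp(-t/tau)."""
        params, x0 = csan
        frozen = ModelParameters(params.currents, params.gL, params.ErevL, Cm=1e12)
        tr = simulate(
            frozen, x0, StimulusProtocol.spontaneous(), 0.2, 1e-3,
            record_gates=True, rtol=1e-9, atol=1e-11,
        )
        Em = x0.Em
        gates = [g for c in params.currents for g in (c.p_gate, c.q_gate)]
        for k, gp in enumerate(gates):
            ginf, tau = gate_equilibrium(Em, gp)
            expected = ginf + (x0.gates[k] - ginf) * np.exp(-tr.t / tau)
            np.testing.assert_allclose(tr.gates[:, k], expected, atol=1e-6)

    def test_gates_stay_in_unit_interval(self, csan_trace):
        assert csan_trace.gates is None  # not recorded by default
        params, x0 = ionfit.io.minimal_cell("cSAN")
        tr = simulate(params, x0, StimulusProtocol.spontaneous(), 1.0, 1e-3,
                      record_gates=True)
        assert tr.gates.min() >= 0.0 and tr.gates.max() <= 1.0

    def test_tolerance_convergence(self, csan):
        """Tightening solver tolerances tenfold moves Em by < 0.1 mV."""
        params, x0 = csan
        proto = StimulusProtocol.spontaneous()
        a = simulate(params, x0, proto, 1.0, 1e-3, rtol=1e-6, atol=1e-8)
        b = simulate(params, x0, proto, 1.0, 1e-3, rtol=1e-7, atol=1e-9)
        assert np.max(np.abs(a.Em - b.Em)) < 0.1

    def test_restitution(self):
        """Shorter pacing intervals shorten the atrial AP (five-current
        uniformly paced model)."""
        params, states = ionfit.io.la_uniform_run("run1")
        apd = {}
        for key, pi in (("PI400", 0.4), ("PI200", 0.2)):
            proto = StimulusProtocol.uniform(pi, int(2.0 / pi), 13.0, first_onset=0.01)
            tr = simulate(params, states[key], proto, 2.0, 2e-4)
            feats = extract_features(tr, discard=pi + 0.01)
            apd[key] = np.nanmean(feats.apd90)
        assert apd["PI200"] < apd["PI400"]

    def test_atrial_model_quiescent_without_stimulus(self):
        """The RA cell lacks a pacemaker phase: no APs unless paced."""
        params, x0 = ionfit.io.minimal_cell("RA")
        tr = simulate(params, x0, StimulusProtocol.spontaneous(), 2.0, 1e-3)
        assert extract_features(tr, discard=0.2).n_cycles == 0
        proto = StimulusProtocol.uniform(0.4, 4, amplitude=30.0)
        tr = simulate(params, x0, proto, 2.0, 1e-3)
        assert extract_features(tr, discard=0.4).n_cycles >= 2

    def test_zero_duration_rejected(self, csan):
        params, x0 = csan
        with pytest.raises(ValueError):
            simulate(params, x0, StimulusProtocol.spontaneous(), 0.0)


class TestPhasePlot:
    def test_constant_and_linear(self):
        t = np.linspace(0, 1, 101)
        _, dv = phase_plot(Trace(t, np.full_like(t, -60.0)))
        np.testing.assert_allclose(dv, 0.0)
        _, dv = phase_plot(Trace(t, t.copy()))
        np.testing.assert_allclose(dv, 1.0)

    def test_sine_derivative_bound(self):
        t = np.arange(0, 1.0, 5e-5)  # 20 kHz, 1 Hz sine, 1 mV amplitude
        v, dv = phase_plot(Trace(t, np.sin(2 * np.pi * t)))
        assert np.max(dv) == pytest.approx(2 * np.pi, rel=1e-3)


class TestRmsError:
    def test_zero_for_identical(self):
        t = np.linspace(0, 1, 50)
        tr = Trace(t, np.sin(t))
        assert rms_error(tr, tr) == 0.0

    def test_constant_offset(self):
        t = np.linspace(0, 1, 50)
        assert rms_error(Trace(t, np.zeros(50)), Trace(t, np.full(50, 2.0))) == 2.0

    def test_masked_samples_ignored(self):
        t = np.linspace(0, 1, 50)
        w = np.ones(50)
        w[10:20] = 0.0
        model = Trace(t, np.zeros(50))
        data = np.zeros(50)
        data[10:20] = 100.0  # artifact only where masked
        assert rms_error(model, Trace(t, data, w)) == 0.0

    def test_invariant_to_adding_masked_samples(self):
        t = np.linspace(0, 1, 50)
        model = Trace(t, np.zeros(50))
        base = Trace(t, np.sin(t))
        masked_w = np.ones(50)
        masked_w[::5] = 0.0
        sub = np.flatnonzero(masked_w)
        ref = rms_error(
            Trace(t[sub], np.zeros(sub.size)), Trace(t[sub], np.sin(t[sub]))
        )
        assert rms_error(model, Trace(t, base.Em, masked_w)) == pytest.approx(ref)

    def test_all_masked_is_error(self):
        t = np.linspace(0, 1, 10)
        with pytest.raises(ValueError):
            rms_error(Trace(t, np.zeros(10)), Trace(t, np.ones(10), np.zeros(10)))

    def test_grid_mismatch_is_error(self):
        with pytest.raises(ValueError):
            rms_error(
                Trace(np.linspace(0, 1, 10), np.zeros(10)),
                Trace(np.linspace(0, 2, 10), np.zeros(10)),
            )


class TestFeatures:
    def test_known_period_square_train(self):
        # synthetic AP-like train with 0.4 s period and fast upstrokes
        t = np.arange(0, 3.0, 1e-4)
        v = np.full_like(t, -80.0)
        for onset in np.arange(0.1, 2.9, 0.4):
            v[(t >= onset) & (t < onset + 0.15)] = 20.0
        feats = extract_features(Trace(t, v), discard=0.2)
        np.testing.assert_allclose(feats.cycle_length, 0.4, atol=1e-3)
        assert np.all(feats.overshoot >= feats.max_diastolic_potential)

    def test_constant_trace_has_no_cycles(self):
        t = np.linspace(0, 2, 1000)
        feats = extract_features(Trace(t, np.full_like(t, -70.0)))
        assert feats.n_cycles == 0

    def test_spontaneous_csan_cycles(self, csan_trace):
        feats = extract_features(csan_trace, discard=0.5)
        assert feats.n_cycles >= 2
        assert np.all(feats.max_diastolic_potential < feats.overshoot)
        assert feats.current_peaks.shape == (feats.n_cycles, 2)

    def test_trace_csv_round_trip(self, tmp_path, csan_trace):
        path = tmp_path / "trace.csv"
        sub = Trace(csan_trace.t[:100], csan_trace.Em[:100])
        sub.to_csv(path)
        again = Trace.from_csv(path)
        np.testing.assert_allclose(again.Em, sub.Em)
        np.testing.assert_allclose(again.weights, 1.0)
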