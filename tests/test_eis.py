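"""Equivalent-circuit impedance: forward model, multisine FFT path, fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal

import memdiel as m
from memdiel.eis import schroeder_phases


class TestCircuitImpedance:
    def test_dc_limit_is_total_resistance(self, control_circuit):
        z = m.circuit_impedance(control_circuit, 1e-9)
        total = control_circuit.r_s_ohm + control_circuit.r_blm_ohm
        assert z.real == pytest.approx(total, rel=1e-6)

    def test_high_frequency_limit_is_series_resistance(self, control_circuit):
        z = m.circuit_impedance(control_circuit, 1e12)
        assert z.real == pytest.approx(control_circuit.r_s_ohm, rel=1e-6)

    def test_control_value_at_window_edge(self, control_circuit):
        """Independent nodal-analysis cross-check at 1.5 Hz."""
        omega = 2 * math.pi * 1.5
        c_tot = control_circuit.c_blm_f + control_circuit.c_tm_f
        # nodal: current through parallel admittance, solved by hand
        y = complex(1 / control_circuit.r_blm_ohm, omega * c_tot)
        z_nodal = control_circuit.r_s_ohm + y.conjugate() / abs(y) ** 2
        z = m.circuit_impedance(control_circuit, 1.5)
        assert z == pytest.approx(z_nodal, rel=1e-12)
        assert z.real == pytest.approx(4.44e7, rel=2e-3)
        assert z.imag == pytest.approx(-8.85e8, rel=2e-3)

    def test_kramers_kronig_shape(self, control_circuit):
        """Single-relaxation circuit: −Im Z ≥ 0 and Re Z monotone
        decreasing in frequency."""
        f = np.geomspace(1e-3, 1e6, 200)
        z = m.circuit_impedance(control_circuit, f)
        assert np.all(z.imag < 0)
        assert np.all(np.diff(z.real) < 0)

    def test_rejects_nonpositive_frequency(self, control_circuit):
        with pytest.raises(ValueError):
            m.circuit_impedance(control_circuit, 0.0)


class TestNyquistGeometry:
    def test_control_apex_and_diameter(self, control_circuit):
        f_star, diameter = m.nyquist_geometry(control_circuit)
        assert f_star == pytest.approx(0.075, abs=5e-4)
        assert diameter == pytest.approx(1.775e10, rel=1e-6)

    def test_scaling_with_membrane_resistance(self, control_circuit):
        import dataclasses
        doubled = dataclasses.replace(
            control_circuit, r_blm_ohm=2 * control_circuit.r_blm_ohm
        )
        f1, d1 = m.nyquist_geometry(control_circuit)
        f2, d2 = m.nyquist_geometry(doubled)
        assert f2 == pytest.approx(f1 / 2)
        assert d2 == pytest.approx(2 * d1)

    @settings(deadline=None, max_examples=50)
    @given(
        st.floats(1e-12, 1e-9),   # C_BLM, F
        st.floats(1e6, 1e12),     # R_BLM, Ω
        st.floats(1e3, 1e6),      # R_s, Ω
    )
    def test_apex_identity(self, c_blm, r_blm, r_s):
        """−Im Z at the apex frequency equals R_BLM/2 for any circuit."""
        p = m.CircuitParams(c_blm_f=c_blm, r_blm_ohm=r_blm, r_s_ohm=r_s)
        f_star, _ = m.nyquist_geometry(p)
        z = m.circuit_impedance(p, f_star)
        assert -z.imag == pytest.approx(r_blm / 2, rel=1e-9)


def _small_spec(**kw):
    defaults = dict(
        excited_freqs_hz=(1.5, 4.0, 12.0, 40.0, 120.0, 400.0, 1200.0, 2000.0),
        sample_rate_hz=8192.0,
        n_samples=16384,
    )
    defaults.update(kw)
    return m.MultisineSpec(**defaults)


class TestMakeMultisine:
    def test_single_tone_peak_to_peak(self):
        spec = _small_spec(excited_freqs_hz=(8.0,), amplitude_v_pp=0.010)
        v = m.make_multisine(spec)
        assert v.max() - v.min() == pytest.approx(0.010, rel=0.01)

    def test_coherent_sampling_has_no_leakage(self):
        spec = _small_spec()
        v = m.make_multisine(spec)
        vf = np.abs(np.fft.rfft(v))
        excited = spec.bins
        mask = np.ones(vf.size, dtype=bool)
        mask[excited] = False
        mask[0] = False
        assert vf[mask].max() < 1e-10 * vf[excited].min()

    def test_schroeder_beats_zero_phase_crest_factor(self):
        spec_s = _small_spec()
        spec_0 = _small_spec(phases_rad=(0.0,) * 8)
        crest = lambda v: np.abs(v).max() / np.sqrt(np.mean(v**2))
        assert crest(m.make_multisine(spec_s)) < crest(m.make_multisine(spec_0))

    def test_non_coherent_frequency_rejected(self):
        with pytest.raises(ValueError, match="coherent|integer multiple"):
            _small_spec(excited_freqs_hz=(1.5, 3.3333))


class TestSimulateFftEis:
    def test_zero_noise_matches_analytic_impedance(self, control_circuit):
        spec = m.coherent_log_grid()
        out = m.simulate_fft_eis(control_circuit, spec, noise_frac=0.0)
        z_ref = m.circuit_impedance(control_circuit, out.freq_hz)
        rel = np.abs(out.z_ohm - z_ref) / np.abs(z_ref)
        assert rel.max() < 1e-8

    def test_grid_covers_measurement_window(self):
        spec = m.coherent_log_grid()
        f = np.asarray(spec.excited_freqs_hz)
        assert f.min() == pytest.approx(1.5)
        assert f.max() == pytest.approx(50e3)
        assert len(f) == 30

    def test_noise_scatter_matches_noise_frac(self, control_circuit):
        """Per-bin relative scatter of |Z| ≈ noise_frac over seeds."""
        spec = _small_spec()
        mags = []
        for seed in range(200):
            out = m.simulate_fft_eis(control_circuit, spec,
                                     noise_frac=0.01, seed=seed)
            mags.append(np.abs(out.z_ohm))
        mags = np.array(mags)
        rel_scatter = mags.std(axis=0) / mags.mean(axis=0)
        assert np.all(rel_scatter > 0.005)
        assert np.all(rel_scatter < 0.02)

    def test_deterministic_per_seed(self, control_circuit):
        spec = _small_spec()
        a = m.simulate_fft_eis(control_circuit, spec, 0.01, seed=5)
        b = m.simulate_fft_eis(control_circuit, spec, 0.01, seed=5)
        assert np.array_equal(a.z_ohm, b.z_ohm)

    def test_agrees_with_time_domain_state_space_oracle(self, control_circuit):
        """The FFT measurement path must reproduce the impedance obtained
        by brute-force time-domain simulation of the circuit ODE
        (state-space lsim at high oversampling, then decimation)."""
        spec = _small_spec(
            excited_freqs_hz=(1.5, 4.0, 12.0, 40.0, 120.0),
            sample_rate_hz=2048.0,
            n_samples=4096,
        )
        out = m.simulate_fft_eis(control_circuit, spec, noise_frac=0.0)

        p = control_circuit
        c_tot = p.c_blm_f + p.c_tm_f
        # state: capacitor voltage v_c;  i = (v - v_c)/R_s
        a = -(1 / p.r_s_ohm + 1 / p.r_blm_ohm) / c_tot
        b = 1 / (p.r_s_ohm * c_tot)
        sys = signal.StateSpace([[a]], [[b]],
                                [[-1 / p.r_s_ohm]], [[1 / p.r_s_ohm]])
        over = 64
        lead = 4096  # fine-grid lead-in absorbing the start-up transient
        n_hi = spec.n_samples * over + lead
        t_hi = np.arange(n_hi) / (spec.sample_rate_hz * over)
        v_fn = m.make_multisine(spec)
        # rebuild the excitation analytically on the fine grid
        phases = schroeder_phases(len(spec.excited_freqs_hz))
        v_hi = np.zeros(n_hi)
        for f0, ph in zip(spec.excited_freqs_hz, phases):
            v_hi += np.cos(2 * np.pi * f0 * t_hi + ph)
        v_hi *= (v_fn.max() - v_fn.min()) / (v_hi.max() - v_hi.min())
        _, i_hi, _ = signal.lsim(sys, v_hi, t_hi)
        # the common time offset cancels in the bin-wise ratio V/I
        v_lo, i_lo = v_hi[lead::over], i_hi[lead::over]
        bins = spec.bins
        z_time = np.fft.rfft(v_lo)[bins] / np.fft.rfft(i_lo)[bins]
        order = np.argsort(np.asarray(spec.excited_freqs_hz))
        rel = np.abs(z_time[order] - out.z_ohm) / np.abs(out.z_ohm)
        assert rel.max() < 1e-3


class TestFitCircuit:
    def test_noiseless_exact_recovery(self, control_circuit):
        spec = _small_spec()
        out = m.simulate_fft_eis(control_circuit, spec, noise_frac=0.0)
        fit = m.fit_circuit(out)
        assert fit.params.c_blm_f == pytest.approx(
            control_circuit.c_blm_f, rel=1e-6)
        assert fit.params.r_blm_ohm == pytest.approx(
            control_circuit.r_blm_ohm, rel=1e-6)
        assert fit.params.r_s_ohm == pytest.approx(
            control_circuit.r_s_ohm, rel=1e-6)
        assert fit.gf == pytest.approx(1.0, abs=1e-9)

    def test_specific_quantities_scale_with_area(self, control_circuit):
        spec = _small_spec()
        out = m.simulate_fft_eis(control_circuit, spec, noise_frac=0.0)
        fit = m.fit_circuit(out)
        assert fit.cm_specific_uF_cm2 == pytest.approx(0.79, rel=1e-5)
        assert fit.rm_specific_ohm_cm2 == pytest.approx(1.42e6, rel=1e-5)

    def test_noisy_recovery_small_sample(self, control_circuit):
        """Short Monte-Carlo sanity check (the full 100-seed study runs in
        the acceptance suite)."""
        spec = m.coherent_log_grid()
        cms = []
        for seed in range(10):
            out = m.simulate_fft_eis(control_circuit, spec,
                                     noise_frac=0.01, seed=seed)
            cms.append(m.fit_circuit(out).cm_specific_uF_cm2)
        assert abs(np.mean(cms) - 0.79) / 0.79 < 0.02

    def test_omitting_teflon_capacitance_biases_cblm(self, control_circuit):
        """Fitting with C_TM forced ~0 absorbs the Teflon capacitance into
        C_BLM: the recovered value rises by ≈ C_TM."""
        spec = _small_spec()
        out = m.simulate_fft_eis(control_circuit, spec, noise_frac=0.0)
        fit = m.fit_circuit(out, c_tm_f=1e-18)
        excess = fit.params.c_blm_f - control_circuit.c_blm_f
        assert excess == pytest.approx(control_circuit.c_tm_f, rel=1e-3)

    def test_too_few_points_rejected(self, control_circuit):
        z = m.circuit_impedance(control_circuit, np.array([1.5, 10.0, 100.0]))
        spec = m.ImpedanceSpectrum(np.array([1.5, 10.0, 100.0]), z)
        with pytest.raises(ValueError, match="4"):
            m.fit_circuit(spec)


class TestWeightedAverage:
    def test_equal_sds_reduce_to_mean(self):
        mean, se = m.weighted_average([1.0, 2.0, 3.0], [0.5, 0.5, 0.5])
        assert mean == pytest.approx(2.0)

    def test_closed_form_two_points(self):
        mean, se = m.weighted_average([1.0, 3.0], [1.0, 1.0])
        assert mean == pytest.approx(2.0)
        assert se == pytest.approx(1 / math.sqrt(2))

    def test_precise_point_dominates(self):
        mean, _ = m.weighted_average([1.0, 3.0], [1e-6, 1.0])
        assert mean == pytest.approx(1.0, abs=1e-5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            m.weighted_average([], [])
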