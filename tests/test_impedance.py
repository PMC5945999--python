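"""Impedance curves and resonance metrics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import zapres as z
from zapres.impedance_analysis import (AnalysisError, ImpedanceCurve,
                                       compute_impedance, smooth_spectrum)
from zapres.resonance_metrics import (MetricError, compare_conditions,
                                      summarize)
from zapres.simulator import Recording

from conftest import run_chirp


def synthetic_curve(f, zmag):
    return ImpedanceCurve(frequency=np.asarray(f, float),
                          magnitude=np.asarray(zmag, float),
                          injection_compartment=0, recording_compartment=0)


class TestSmoothSpectrum:
    def test_window_one_is_identity(self):
        x = np.random.default_rng(0).random(50)
        assert np.array_equal(smooth_spectrum(x, 1), x)

    def test_constant_series_unchanged(self):
        x = np.full(300, 3.7)
        assert np.allclose(smooth_spectrum(x, 100), x)

    def test_impulse_plateau(self):
        """Impulse of length 201 with a 101-point window: plateau 1/101."""
        x = np.zeros(201)
        x[100] = 1.0
        sm = smooth_spectrum(x, 101)
        center = sm[50:151]
        assert np.allclose(center, 1.0 / 101.0)

    def test_window_too_large_rejected(self):
        with pytest.raises(ValueError):
            smooth_spectrum(np.ones(10), 11)

    @given(st.integers(1, 99))
    def test_preserves_mean_of_constant_padding(self, window):
        x = np.linspace(1.0, 2.0, 100)
        sm = smooth_spectrum(x, window)
        assert sm.shape == x.shape
        assert np.all(sm >= x.min() - 1e-12) and np.all(sm <= x.max() + 1e-12)


def _synthetic_resistor_recording(R=50.0):
    """V = I*R exactly, with chirp metadata, 65 s at 10 kHz."""
    t = np.arange(0.0, 67.0 + 1e-4 / 2, 1e-4)
    spec = z.ChirpSpec(amplitude=100.0, compartment=0)
    i_pA = z.chirp_waveform(spec, t - 2.0)
    vm = -60.0 + i_pA * 1e-3 * R  # nA * MΩ = mV
    meta = {"stimulus": {"chirps": [{"f_start": 0.0, "f_end": 40.0,
                                     "duration_s": 65.0, "amplitude_pA": 100.0,
                                     "compartment": 0, "onset_ms": 2000.0}]}}
    return Recording(time=t, vm={0: vm}, injected={0: i_pA}, metadata=meta)


class TestComputeImpedance:
    def test_ideal_resistor_is_flat(self):
        curve = compute_impedance(_synthetic_resistor_recording(R=50.0), 0, 0)
        assert np.allclose(curve.magnitude, 50.0, rtol=1e-6)
        assert curve.frequency[0] >= 1.0 and curve.frequency[-1] <= 40.0

    def test_frequency_resolution_metadata(self):
        curve = compute_impedance(_synthetic_resistor_recording(), 0, 0)
        assert curve.metadata["frequency_resolution_Hz"] == pytest.approx(1 / 65.0)
        assert curve.metadata["smoothing_span_Hz"] == pytest.approx(101 / 65.0)

    def test_missing_chirp_metadata_raises(self):
        rec = _synthetic_resistor_recording()
        with pytest.raises(AnalysisError):
            compute_impedance(rec, 5, 0)

    def test_ratio_smoothing_mode(self):
        rec = _synthetic_resistor_recording(R=80.0)
        curve = compute_impedance(rec, 0, 0, smoothing_mode="ratio")
        assert np.allclose(curve.magnitude, 80.0, rtol=1e-5)

    def test_amplitude_invariance_linear_regime(self, passive_one, config):
        curves = []
        for amp in (50.0, 25.0):
            rec = run_chirp(passive_one, 0, amp, config)
            curves.append(compute_impedance(rec, 0, 0).magnitude)
        assert np.max(np.abs(curves[0] - curves[1]) / curves[1]) < 0.01


class TestResonanceSummary:
    def test_flat_curve(self):
        f = np.linspace(1, 40, 200)
        s = summarize(synthetic_curve(f, np.full(200, 10.0)))
        assert s.q == s.d == s.quality == 1.0
        assert not s.resonant

    def test_monotone_increasing_high_pass(self):
        f = np.linspace(1, 40, 200)
        s = summarize(synthetic_curve(f, np.linspace(5, 20, 200)))
        assert s.f_res == pytest.approx(40.0)
        assert not s.resonant
        assert s.quality == pytest.approx(1.0)

    def test_known_band_pass_arithmetic(self):
        """Z1=40, Zres=80 at 10 Hz, Z40=20 -> Q=2, D=0.5, quality=4."""
        f = np.linspace(1, 40, 391)
        base = 40.0 - (f - 1.0) / 39.0 * 20.0  # 40 MΩ at 1 Hz -> 20 MΩ at 40 Hz
        bump = (80.0 - (40.0 - 20.0 * 9.0 / 39.0)) * np.exp(-((f - 10.0) / 4.0) ** 2)
        curve = synthetic_curve(f, base + bump)
        s = summarize(curve)
        assert s.z_1 == pytest.approx(40.0, abs=0.5)
        assert s.z_40 == pytest.approx(20.0, abs=0.5)
        assert s.f_res == pytest.approx(10.0, abs=0.5)
        assert s.q == pytest.approx(2.0, abs=0.05)
        assert s.d == pytest.approx(0.5, abs=0.01)
        assert s.quality == pytest.approx(4.0, abs=0.1)
        assert s.resonant

    def test_tie_breaks_to_lowest_frequency(self):
        f = np.linspace(1, 40, 40)
        z_ = np.ones(40)
        z_[10] = z_[20] = 2.0
        assert summarize(synthetic_curve(f, z_)).f_res == pytest.approx(f[10])

    def test_non_finite_rejected(self):
        f = np.linspace(1, 40, 50)
        bad = np.ones(50)
        bad[10] = np.nan
        with pytest.raises(MetricError):
            summarize(synthetic_curve(f, bad))

    @given(st.floats(0.1, 10.0))
    def test_scaling_invariance(self, factor):
        f = np.linspace(1, 40, 200)
        z_ = 10.0 + 30.0 * np.exp(-((f - 12.0) / 5.0) ** 2)
        a = summarize(synthetic_curve(f, z_))
        b = summarize(synthetic_curve(f, z_ * factor))
        assert b.f_res == a.f_res and b.hb == a.hb
        assert b.quality == pytest.approx(a.quality, rel=1e-12)
        assert b.z_res == pytest.approx(a.z_res * factor, rel=1e-12)

    def test_quality_identity(self):
        rng = np.random.default_rng(42)
        f = np.linspace(1, 40, 300)
        for _ in range(20):
            z_ = 1.0 + rng.random(300).cumsum() / 50.0
            s = summarize(synthetic_curve(f, z_))
            assert s.quality == s.z_res / s.z_40
            assert s.quality == pytest.approx(s.q / s.d, rel=1e-12)

    def test_band_pass_oracle(self):
        """f_res and HB against a continuous-optimizer oracle on a
        quasi-active single-branch (RLC-equivalent) magnitude curve."""
        from scipy.optimize import brentq, minimize_scalar
        g, c, w, tau = 0.02, 0.2, 0.05, 30.0  # µS, nF, µS, ms

        def zmag(f_hz):
            om = 2e-3 * np.pi * f_hz
            return 1.0 / abs(g + 1j * om * c + w / (1 + 1j * om * tau))

        res = minimize_scalar(lambda f: -zmag(f), bounds=(1.0, 40.0),
                              method="bounded")
        f_peak = res.x
        zmax = zmag(f_peak)
        lo = brentq(lambda f: zmag(f) - zmax / np.sqrt(2), 1.0, f_peak)
        hi = brentq(lambda f: zmag(f) - zmax / np.sqrt(2), f_peak, 40.0)

        f = np.arange(1.0, 40.0 + 1e-9, 1 / 65.0)
        s = summarize(synthetic_curve(f, zmag(f)))
        step = 1 / 65.0
        assert abs(s.f_res - f_peak) <= step
        assert abs(s.hb - (hi - lo)) <= 2 * step


class TestCompareConditions:
    def test_identical_summaries_give_zero(self):
        f = np.linspace(1, 40, 100)
        s = summarize(synthetic_curve(f, 10 + np.exp(-((f - 8) / 3) ** 2)))
        d = compare_conditions(s, s)
        assert d["quality_change_pct"] == 0.0
        assert d["f_res_change_Hz"] == 0.0

    def test_quality_drop_percentage(self):
        f = np.linspace(1, 40, 400)

        def curve(quality):
            # flat 10 MΩ with a bump at 10 Hz so Zres/Z40 == quality
            z_ = np.full(400, 10.0)
            z_ += (quality * 10.0 - 10.0) * np.exp(-((f - 10.0) / 2.0) ** 2)
            return summarize(synthetic_curve(f, z_))

        d = compare_conditions(curve(4.0), curve(3.08))
        assert d["quality_change_pct"] == pytest.approx(-23.0, abs=0.3)

    def test_f_res_shift(self):
        f = np.linspace(1, 40, 400)
        a = summarize(synthetic_curve(f, 10 + 5 * np.exp(-((f - 10) / 2) ** 2)))
        b = summarize(synthetic_curve(f, 10 + 5 * np.exp(-((f - 8) / 2) ** 2)))
        assert compare_conditions(a, b)["f_res_change_Hz"] == pytest.approx(-2.0, abs=0.15)

    def test_mismatched_conditions_rejected(self):
        f = np.linspace(1, 40, 100)
        s = summarize(synthetic_curve(f, np.full(100, 5.0)))
        with pytest.raises(ValueError):
            compare_conditions(s, s,
                               meta_a={"injection_compartment": 2,
                                       "recording_compartment": 2,
                                       "hold_condition": {2: -80.0},
                                       "hot_zone": True},
                               meta_b={"injection_compartment": 5,
                                       "recording_compartment": 2,
                                       "hold_condition": {2: -80.0},
                                       "hot_zone": False})
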