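"""Stimulus waveforms and DC-hold calibration."""

import numpy as np
import pytest

import zapres as z
from zapres.stimulation import (CalibrationError, ChirpSpec, EPSPLikeSpec,
                                HoldSpec, PulseSpec, StimulusProgram,
                                calibrate_hold, chirp_waveform, epsp_waveform,
                                joint_calibrate)

from conftest import make_passive_model


class TestChirp:
    def test_starts_at_zero(self):
        assert chirp_waveform(ChirpSpec(), 0.0) == 0.0

    def test_silent_outside_window(self):
        spec = ChirpSpec()
        assert chirp_waveform(spec, -0.1) == 0.0
        assert chirp_waveform(spec, 65.1) == 0.0

    def test_instantaneous_frequency_reaches_f_end(self):
        """Phase derivative at t = 65 s equals 40 Hz."""
        spec = ChirpSpec()
        # d/dt [f0 t + (f1-f0) t^2 / (2T)] = f0 + (f1-f0) t/T
        f_inst = spec.f_start + (spec.f_end - spec.f_start) * 65.0 / spec.duration
        assert f_inst == pytest.approx(40.0)

    def test_zero_crossing_count(self):
        """A 0->f1 chirp over T sweeps f1*T/2 cycles => ~f1*T crossings."""
        spec = ChirpSpec(f_end=40.0, duration=65.0)
        t = np.arange(0.0, 65.0, 1e-3)
        w = chirp_waveform(spec, t)
        crossings = int(np.sum(np.sign(w[:-1]) != np.sign(w[1:])))
        assert abs(crossings - round(40.0 * 65.0)) <= 1

    def test_spectrum_covers_band(self):
        """Finite energy with nonzero Fourier magnitude across (0, 40] Hz."""
        spec = ChirpSpec()
        t = np.arange(0.0, 65.0, 1e-3)
        w = chirp_waveform(spec, t)
        freqs = np.fft.rfftfreq(w.size, d=1e-3)
        mag = np.abs(np.fft.rfft(w))
        band = (freqs >= 1.0) & (freqs <= 40.0)
        assert np.all(mag[band] > 0)

    def test_validation(self):
        with pytest.raises(ValueError):
            ChirpSpec(f_start=40.0, f_end=10.0)
        with pytest.raises(ValueError):
            ChirpSpec(amplitude=-5.0)


class TestEPSP:
    def test_peak_value_and_location(self):
        spec = EPSPLikeSpec()  # 1 nA peak, 5 ms delay, tau 2 ms
        t = np.arange(0.0, 60.0, 0.001)
        w = epsp_waveform(spec, t)
        assert w.max() == pytest.approx(1.0, rel=1e-4)
        assert t[np.argmax(w)] == pytest.approx(5.0 + 2.0, abs=0.01)

    def test_zero_before_onset(self):
        assert epsp_waveform(EPSPLikeSpec(), 4.9) == 0.0
        assert epsp_waveform(EPSPLikeSpec(), 14.9, reference_onset=10.0) == 0.0


def test_pulse_render():
    program = StimulusProgram(duration_ms=20.0,
                              pulses=[PulseSpec(amplitude=3.0, onset=5.0,
                                                duration=5.0, compartment=2)])
    cur = program.render(0.1, 200)[2]
    assert cur[45] == 0.0 and cur[55] == 3.0 and cur[105] == 0.0
    assert np.sum(cur > 0) == 50


class TestCalibration:
    def test_rest_needs_no_current(self, hot_model, config):
        rest = z.run(hot_model, StimulusProgram(duration_ms=config.settle_time
                                                * 1e3), config,
                     record=[2]).vm[2][-1]
        current = calibrate_hold(hot_model, HoldSpec(2, float(rest)), config)
        assert abs(current) < 1.0  # pA

    def test_passive_compartment_obeys_ohms_law(self, passive_one, config):
        # R = 100 MΩ: +10 mV needs +100 pA
        current = calibrate_hold(passive_one, HoldSpec(0, -60.0), config)
        assert current == pytest.approx(100.0, rel=0.05)

    def test_hyperpolarizing_hold_needs_negative_current(self, hot_model, config):
        current = calibrate_hold(hot_model, HoldSpec(2, -80.0), config)
        assert current < 0

    def test_unreachable_target_raises(self, passive_one, config):
        with pytest.raises(ValueError):
            calibrate_hold(passive_one, HoldSpec(0, 5000.0), config)

    def test_monotone_in_target(self, hot_model, config):
        currents = [calibrate_hold(hot_model, HoldSpec(2, vm), config)
                    for vm in (-80.0, -65.0, -50.0)]
        assert currents[0] < currents[1] < currents[2]


class TestJointCalibration:
    def test_both_at_rest(self, hot_model, config):
        rec = z.run(hot_model, StimulusProgram(duration_ms=config.settle_time
                                               * 1e3), config, record=[2, 18])
        ia, ib = joint_calibrate(
            hot_model, HoldSpec(2, float(rec.vm[2][-1]), tolerance=0.5),
            HoldSpec(18, float(rec.vm[18][-1]), tolerance=0.5), config)
        assert abs(ia) < 5.0 and abs(ib) < 5.0

    def test_passive_pair_matches_linear_system(self, config):
        """Currents solve the 2x2 conductance system analytically."""
        model = make_passive_model(2, diameter=1.0, length=300.0,
                                   leak_density=5e-4)
        from zapres.simulator import _compiled
        cm = _compiled(model)
        g0 = model.density(0, "leak") * model.compartments[0].area_cm2 * 1e6
        g1 = model.density(1, "leak") * model.compartments[1].area_cm2 * 1e6
        a = cm.a_uS[1]
        targets = np.array([5.0, -8.0])  # mV above/below rest
        G = np.array([[g0 + a, -a], [-a, g1 + a]])
        expected = G @ targets * 1e3  # nA -> pA
        ia, ib = joint_calibrate(model,
                                 HoldSpec(0, -70.0 + 5.0, tolerance=0.1),
                                 HoldSpec(1, -70.0 - 8.0, tolerance=0.1),
                                 config)
        assert ia == pytest.approx(expected[0], rel=0.08, abs=2.0)
        assert ib == pytest.approx(expected[1], rel=0.08, abs=2.0)

    def test_distal_hold_leaves_soma_near_rest(self, hot_model, config):
        """Depolarizing the distal dendrite requires almost no somatic current."""
        ia, ib = joint_calibrate(hot_model, HoldSpec(2, -65.0),
                                 HoldSpec(18, -40.0), config)
        assert abs(ia) < 0.25 * abs(ib)

    def test_same_compartment_rejected(self, hot_model, config):
        with pytest.raises(ValueError):
            joint_calibrate(hot_model, HoldSpec(2, -70.0), HoldSpec(2, -60.0),
                            config)
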