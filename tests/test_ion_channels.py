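"""Gating kinetics: steady states, time constants, the modified M current."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from zapres.ion_channels import (CHANNEL_NAMES, CalciumPool, GateSpec,
                                 build_modified_KM, channel_current,
                                 channels_from_params, gate_steady_state,
                                 gate_tau, tau_maximum)

VGRID = np.arange(-120.0, 40.0 + 0.5, 0.5)


@pytest.fixture(scope="module")
def channels(default_params):
    return channels_from_params(default_params)


@pytest.fixture(scope="module")
def modified_km(channels):
    return build_modified_KM(channels["g_K(M)"], 15.0, 40.0)


def all_gates(channels):
    for name, spec in channels.items():
        for gate in spec.gates:
            yield name, gate


def test_steady_state_bounded_and_monotone(channels):
    for name, gate in all_gates(channels):
        vals = gate_steady_state(gate, VGRID)
        assert np.all((vals >= 0) & (vals <= 1)), f"{name}.{gate.name}"
        diffs = np.diff(vals)
        if gate.kind == "activation":
            assert np.all(diffs >= -1e-12), f"{name}.{gate.name} not increasing"
        else:
            assert np.all(diffs <= 1e-12), f"{name}.{gate.name} not decreasing"


def test_time_constant_positive_and_continuous(channels):
    fine = np.arange(-120.0, 40.0, 0.1)
    for name, gate in all_gates(channels):
        taus = gate_tau(gate, fine)
        assert np.all(taus > 0), f"{name}.{gate.name}"
        ratio = taus[1:] / taus[:-1]
        assert np.all((ratio < 10) & (ratio > 0.1)), f"{name}.{gate.name} jump"


def test_activation_gate_limits(channels):
    m = channels["g_Na(F)"].gate("m")
    assert gate_steady_state(m, -120.0) < 0.01
    assert gate_steady_state(m, m.v_half) == pytest.approx(0.5, abs=1e-12)


def test_low_threshold_ca_window_overlap(channels):
    """Activation and inactivation curves overlap between -80 and -65 mV."""
    spec = channels["g_Ca(L)"]
    v = np.arange(-80.0, -64.9, 0.5)
    product = (gate_steady_state(spec.gate("m"), v)
               * gate_steady_state(spec.gate("h"), v))
    assert product.max() > 0.01


def test_hcn_closed_above_minus_sixty(channels):
    """g_h activates only below about -60 mV."""
    gate = channels["g_h"].gates[0]
    assert gate_steady_state(gate, -50.0) < 0.05


def test_high_threshold_ca_tau_peak(channels):
    """The g_Ca(H) activation time constant peaks at 2.1 ms near -20 mV."""
    v_at_max, tau_max = tau_maximum(channels["g_Ca(H)"].gates[0], dv=0.1)
    assert tau_max == pytest.approx(2.1, abs=0.01)
    assert v_at_max == pytest.approx(-20.0, abs=0.5)


class TestModifiedKM:
    def test_zero_modification_is_identity(self, channels):
        same = build_modified_KM(channels["g_K(M)"], 0.0, 0.0)
        assert same == channels["g_K(M)"]

    def test_shift_only_increases_activation(self, channels, modified_km):
        base = channels["g_K(M)"].gates[0]
        mod = modified_km.gates[0]
        grid = np.arange(-120.0, 40.0 + 1.0, 1.0)
        assert np.all(gate_steady_state(mod, grid)
                      >= gate_steady_state(base, grid) - 1e-12)

    def test_shift_bounded_and_localized(self, channels, modified_km):
        base = channels["g_K(M)"].gates[0]
        mod = modified_km.gates[0]
        grid = np.arange(-120.0, 40.0 + 1.0, 1.0)
        b = gate_steady_state(base, grid)
        m = gate_steady_state(mod, grid)
        # effective voltage displacement never exceeds the 15 mV budget
        shifted = gate_steady_state(base, grid + 15.0)
        assert np.all(m <= shifted + 1e-9)
        # at strongly depolarized potentials the shift is below 1 mV
        assert (gate_steady_state(mod, 40.0)
                <= gate_steady_state(base, 41.0) + 1e-9)

    def test_tau_maximum_reduced_exactly(self, channels, modified_km):
        _, base_max = tau_maximum(channels["g_K(M)"].gates[0])
        _, mod_max = tau_maximum(modified_km.gates[0])
        assert mod_max == pytest.approx(base_max - 40.0, rel=1e-9)

    def test_rejects_other_channels(self, channels):
        with pytest.raises(ValueError):
            build_modified_KM(channels["g_h"], 15.0, 40.0)


class TestChannelCurrent:
    def test_zero_conductance(self, channels):
        spec = channels["g_K(M)"]
        assert channel_current(spec, 0.0, -20.0, (0.7,)) == 0.0

    def test_zero_driving_force(self, channels):
        spec = channels["g_K(DR)"]
        assert channel_current(spec, 0.01, spec.reversal, (1.0,)) == 0.0

    def test_leak_is_ohmic(self, channels):
        leak = channels["leak"]
        i = channel_current(leak, 2e-5, leak.reversal + 10.0)
        assert i == pytest.approx(2e-5 * 10.0)

    def test_outward_positive_sign(self, channels):
        spec = channels["g_K(DR)"]  # E_K below V -> outward, positive
        assert channel_current(spec, 0.01, -20.0, (0.5,)) > 0

    def test_rejects_out_of_range_gate(self, channels):
        with pytest.raises(ValueError):
            channel_current(channels["g_K(DR)"], 0.01, 0.0, (1.5,))


def test_exponential_relaxation_matches_closed_form(channels):
    """Rush-Larsen stepping reproduces x(t) = x_inf + (x0-x_inf)e^{-t/tau}."""
    gate = channels["g_K(M)"].gates[0]
    v, dt = -50.0, 0.025
    xinf, tau = float(gate_steady_state(gate, v)), float(gate_tau(gate, v))
    x = 0.9
    factor = np.exp(-dt / tau)
    for _ in range(4000):  # 100 ms
        x = xinf + (x - xinf) * factor
    exact = xinf + (0.9 - xinf) * np.exp(-100.0 / tau)
    assert x == pytest.approx(exact, rel=1e-3)


def test_calcium_pool_validation():
    pool = CalciumPool(influx_scale=1.0, decay_tau=20.0)
    assert pool.concentration == 0.0
    with pytest.raises(ValueError):
        CalciumPool(influx_scale=1.0, decay_tau=0.0)
    with pytest.raises(ValueError):
        CalciumPool(influx_scale=1.0, decay_tau=20.0, concentration=-1.0)


def test_registry_covers_all_channels(channels):
    assert set(CHANNEL_NAMES) <= set(channels)


@given(st.floats(-120, 40), st.floats(-120, 40))
def test_monotone_steady_state_property(default_params, v1, v2):
    gate = channels_from_params(default_params)["g_K(M)"].gates[0]
    lo, hi = sorted((v1, v2))
    assert gate_steady_state(gate, lo) <= gate_steady_state(gate, hi) + 1e-12
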