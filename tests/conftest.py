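import math

import numpy as np
import pytest
from hypothesis import settings

import zapres as z
from zapres.ion_channels import CHANNEL_NAMES, channels_from_params
from zapres.model_build import CompartmentSpec, NeuronModel, load_default_params

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params():
    return load_default_params()


@pytest.fixture(scope="session")
def hot_model():
    return z.build_l5_model(hot_zone=True, resonance_mode=True)


@pytest.fixture(scope="session")
def flat_model():
    return z.build_l5_model(hot_zone=False, resonance_mode=True)


@pytest.fixture(scope="session")
def spiking_model():
    return z.build_l5_model(hot_zone=True, resonance_mode=False)


@pytest.fixture(scope="session")
def config():
    return z.SimConfig()


def make_passive_model(n: int = 1, *, leak_density: float = 1e-4,
                       leak_reversal: float = -70.0, length: float = 56.42,
                       diameter: float = 56.42, axial_resistivity: float = 150.0,
                       cm: float = 1.0) -> NeuronModel:
    """Chain of n identical passive cylinders (leak only).

    The default geometry gives one compartment with R ≈ 100 MΩ and
    C ≈ 100 pF (area 1e-4 cm² at 1 µF/cm²).
    """
    params = load_default_params()
    channels = channels_from_params(params)
    comps = [CompartmentSpec(
        index=i, parent=None if i == 0 else i - 1, length=length,
        diameter=diameter, axial_resistivity=axial_resistivity,
        specific_capacitance=cm, leak_conductance_density=leak_density,
        leak_reversal=leak_reversal, zone="soma" if i == 0 else "apical_trunk")
        for i in range(n)]
    densities = {}
    for c in comps:
        densities[(c.index, "leak")] = leak_density
        for name in CHANNEL_NAMES:
            if name != "leak":
                densities[(c.index, name)] = 0.0
    return NeuronModel(
        compartments=comps, densities=densities, channels=channels,
        hot_zone=False, resonance_mode=True,
        calcium_influx_scale={c.index: 1.0 for c in comps},
        calcium_decay_tau=20.0, kc_saturation=250.0, ahp_ca_half=100.0,
        ahp_tau=400.0)


@pytest.fixture(scope="session")
def passive_one():
    return make_passive_model(1)


@pytest.fixture(scope="session")
def passive_chain():
    return make_passive_model(4, diameter=3.0, length=100.0)


def run_chirp(model, injection, amplitude_pA, config, record=None,
              dc=None, duration_s=65.0):
    """Settle + chirp run returning the Recording."""
    chirp = z.ChirpSpec(amplitude=amplitude_pA, compartment=injection,
                        duration=duration_s)
    settle_ms = config.settle_time * 1e3
    program = z.StimulusProgram(
        duration_ms=settle_ms + duration_s * 1e3, dc=dict(dc or {}),
        chirps=[(chirp, settle_ms)])
    return z.run(model, program, config,
                 record=record or [injection])
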