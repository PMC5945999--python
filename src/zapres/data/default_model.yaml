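# Default parameterization of the reduced layer 5 pyramidal neuron model.
#
# Versioned: every quantitative result of the package is evaluated against
# this file.  Geometry is a ~20-compartment equivalent-cylinder reduction of
# a tufted regular-spiking L5 cell (axon stub 0-1, soma 2, basal cable 3-5,
# apical trunk 6-15, distal apical 16-18, tuft 19).  Kinetic forms are
# Traub-style Hodgkin-Huxley conventions expressed as Boltzmann steady
# states and bi-exponential bell time constants (see ion_channels.GateSpec).
# Dendritic specific capacitance is 2 uF/cm2 (spine-membrane correction);
# soma and axon use 1 uF/cm2.
#
# Units: lengths/diameters um; axial resistivity ohm*cm; capacitance uF/cm2;
# conductance densities S/cm2; voltages mV; time constants ms.

meta:
  version: "1.1"

reversals:
  na: 50.0
  k: -95.0
  ca: 120.0
  h: -35.0
  leak: -76.0

passive:
  axial_resistivity: 150.0
  specific_capacitance: 1.0
  leak_conductance_density: 3.0e-5
  leak_reversal: -76.0
  zones:
    soma: {leak_conductance_density: 5.0e-5}
    axon: {leak_conductance_density: 1.0e-4}
    basal: {specific_capacitance: 2.0}
    apical_trunk: {specific_capacitance: 2.0}
    middle_apical: {specific_capacitance: 2.0, leak_conductance_density: 4.5e-5}
    distal_apical: {specific_capacitance: 2.0, leak_conductance_density: 2.3e-4}
    tuft: {specific_capacitance: 2.0, leak_conductance_density: 7.0e-5}

# index parent length diameter zone
morphology:
  - {index: 0,  parent: 1,  length: 60.0,  diameter: 1.0,  zone: axon}
  - {index: 1,  parent: 2,  length: 30.0,  diameter: 2.0,  zone: axon}
  - {index: 2,  parent: null, length: 35.0, diameter: 25.0, zone: soma}
  - {index: 3,  parent: 2,  length: 80.0,  diameter: 3.0,  zone: basal}
  - {index: 4,  parent: 3,  length: 100.0, diameter: 1.2,  zone: basal}
  - {index: 5,  parent: 4,  length: 110.0, diameter: 0.48, zone: basal}
  - {index: 6,  parent: 2,  length: 100.0, diameter: 5.0,  zone: apical_trunk}
  - {index: 7,  parent: 6,  length: 100.0, diameter: 4.6,  zone: apical_trunk}
  - {index: 8,  parent: 7,  length: 100.0, diameter: 4.2,  zone: apical_trunk}
  - {index: 9,  parent: 8,  length: 100.0, diameter: 3.9,  zone: apical_trunk}
  - {index: 10, parent: 9,  length: 100.0, diameter: 3.6,  zone: middle_apical}
  - {index: 11, parent: 10, length: 100.0, diameter: 3.4,  zone: middle_apical}
  - {index: 12, parent: 11, length: 100.0, diameter: 3.2,  zone: middle_apical}
  - {index: 13, parent: 12, length: 100.0, diameter: 3.1,  zone: middle_apical}
  - {index: 14, parent: 13, length: 100.0, diameter: 3.0,  zone: middle_apical}
  - {index: 15, parent: 14, length: 100.0, diameter: 3.0,  zone: middle_apical}
  - {index: 16, parent: 15, length: 120.0, diameter: 3.2,  zone: distal_apical}
  - {index: 17, parent: 16, length: 120.0, diameter: 3.0,  zone: distal_apical}
  - {index: 18, parent: 17, length: 120.0, diameter: 2.8,  zone: distal_apical}
  - {index: 19, parent: 18, length: 150.0, diameter: 1.3,  zone: tuft}

channels:
  leak:
    reversal: leak
    gates: []
  "g_Na(F)":
    reversal: na
    gates:
      - {name: m, kind: activation, power: 3, v_half: -38.0, slope: 6.0,
         tau: {base: 0.04, amp: 0.4, v_peak: -40.0, sigma: 15.0}}
      - {name: h, kind: inactivation, power: 1, v_half: -48.0, slope: -5.0,
         tau: {base: 0.4, amp: 10.0, v_peak: -55.0, sigma: 12.0}}
  "g_Na(P)":
    reversal: na
    gates:
      - {name: m, kind: activation, power: 1, v_half: -50.0, slope: 4.5,
         tau: {base: 0.3, amp: 1.4, v_peak: -50.0, sigma: 15.0}}
  "g_K(DR)":
    reversal: k
    gates:
      - {name: n, kind: activation, power: 2, v_half: -15.0, slope: 6.0,
         tau: {base: 0.4, amp: 2.4, v_peak: -25.0, sigma: 15.0}}
  "g_K(A)":
    reversal: k
    gates:
      - {name: a, kind: activation, power: 2, v_half: -50.0, slope: 10.0,
         tau: {base: 0.5, amp: 2.0, v_peak: -50.0, sigma: 20.0}}
      - {name: b, kind: inactivation, power: 1, v_half: -75.0, slope: -7.0,
         tau: {base: 10.0, amp: 40.0, v_peak: -70.0, sigma: 15.0}}
  "g_K(M)":
    reversal: k
    gates:
      - {name: m, kind: activation, power: 1, v_half: -30.0, slope: 4.2,
         tau: {base: 2.0, amp: 170.0, v_peak: -30.0, sigma: 30.0}}
  "g_K(C)":
    reversal: k
    ca_dependent: true
    gates:
      - {name: m, kind: activation, power: 1, v_half: -15.0, slope: 9.0,
         tau: {base: 1.0, amp: 4.0, v_peak: -20.0, sigma: 15.0}}
  "g_K(AHP)":
    reversal: k
    ca_dependent: true
    gates: []
  "g_Ca(L)":
    reversal: ca
    gates:
      - {name: m, kind: activation, power: 2, v_half: -56.0, slope: 6.2,
         tau: {base: 2.0, amp: 10.0, v_peak: -65.0, sigma: 15.0}}
      - {name: h, kind: inactivation, power: 1, v_half: -80.0, slope: -6.4,
         tau: {base: 25.0, amp: 90.0, v_peak: -78.0, sigma: 12.0}}
  "g_Ca(H)":
    reversal: ca
    gates:
      - {name: m, kind: activation, power: 2, v_half: -20.0, slope: 5.0,
         tau: {base: 0.3, amp: 3.6, v_peak: -20.0, sigma: 12.0}}
  g_h:
    reversal: h
    gates:
      - {name: m, kind: inactivation, power: 1, v_half: -75.0, slope: -5.5,
         tau: {base: 30.0, amp: 330.0, v_peak: -85.0, sigma: 22.0}}

# Subthreshold variant of g_K(M): activation shifted up to 15 mV toward
# hyperpolarized potentials near the foot of the curve; tau maximum lowered
# by 40 ms.
km_modification:
  max_shift: 15.0
  tau_reduction: 40.0

calcium:
  influx_scale: 2.0e-5   # units*cm2/(nA*ms); per-compartment phi = scale/area
  decay_tau: 20.0        # ms
  kc_saturation: 250.0   # pool units at which g_K(C) scaling saturates
  ahp_ca_half: 100.0     # half-activation of the AHP gate (pool units)
  ahp_tau: 400.0         # ms

hot_zone:
  compartments: [16, 17, 18, 19]
  caH_multiplier: 10.0
  caL_multiplier: 100.0

densities:
  "g_Na(F)":
    default: 0.012
    zones: {soma: 0.2, axon: 0.45, basal: 0.012, distal_apical: 0.025, tuft: 0.015}
  "g_Na(P)":
    default: 2.5e-5
    zones: {soma: 1.8e-4, axon: 1.8e-4, basal: 2.0e-5}
  "g_K(DR)":
    default: 7.0e-4
    zones: {soma: 0.12, axon: 0.25}
  "g_K(A)":
    default: 2.0e-3
    zones: {soma: 5.0e-3}
  "g_K(M)":
    default: 1.1e-3
    zones: {soma: 3.0e-3, axon: 3.0e-3, basal: 2.0e-4,
            apical_trunk: 8.0e-4, middle_apical: 1.0e-3, tuft: 1.0e-3}
  "g_K(C)":
    default: 4.0e-4
    zones: {soma: 1.5e-3}
  "g_K(AHP)":
    default: 2.0e-4
    zones: {soma: 8.0e-4}
  "g_Ca(L)":
    default: 1.0e-5
    zones: {apical_trunk: 6.0e-6, middle_apical: 6.0e-6,
            distal_apical: 6.0e-6, tuft: 6.0e-6}
  "g_Ca(H)":
    default: 3.7e-5
    zones: {apical_trunk: 3.7e-5, middle_apical: 3.7e-5,
            distal_apical: 3.7e-5, tuft: 3.7e-5}
  g_h:
    default: 3.0e-5
    zones: {soma: 5.0e-5, axon: 3.0e-5, basal: 3.0e-5}
    compartments:
      6: 7.0e-5
      7: 9.0e-5
      8: 1.2e-4
      9: 1.5e-4
      10: 1.9e-4
      11: 2.4e-4
      12: 3.0e-4
      13: 3.8e-4
      14: 4.8e-4
      15: 6.0e-4
      16: 9.0e-4
      17: 1.05e-3
      18: 1.2e-3
      19: 1.3e-3
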