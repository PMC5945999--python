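# zapres

Subthreshold membrane **resonance analysis of a reduced layer 5 pyramidal
neuron model** — a compartmental Hodgkin–Huxley model of a tufted L5 cell
with a toggleable distal-apical Ca²⁺ "hot zone", plus the full chirp (ZAP)
impedance toolchain used to characterize its functional zones.

It is intended for computational neuroscientists studying how non-uniform
ion-channel expression divides a pyramidal neuron into frequency-tuned
zones (basal, perisomatic, distal apical, tuft), and how the distal Ca²⁺
hot zone couples the apical and perisomatic spike-initiation regions.

## The model and the measurements

The neuron is a ~20-compartment equivalent-cylinder reduction (axon stub,
soma, basal cable, tapering apical trunk, distal apical dendrite, apical
tuft) carrying eleven Traub-style conductances: g_Na(F), g_Na(P), g_K(DR),
g_K(A), g_K(M) (with a subthreshold modification: activation shifted up to
15 mV toward hyperpolarized potentials near the foot of its curve and its
time-constant maximum reduced by 40 ms), g_K(C), g_K(AHP), g_Ca(L),
g_Ca(H), g_h and leak. The *hot zone* multiplies g_Ca(H) ×10 and g_Ca(L)
×100 in the distal apical/tuft compartments; *resonance mode* removes
g_Na(F) and g_K(AHP) so every response stays subthreshold.

Impedance is measured exactly as in chirp electrophysiology: a DC offset
clamps the target compartment at a holding potential, a linear chirp
current I(t) = A·sin(2π[f₀t + (f₁−f₀)t²/2T]) (0→40 Hz over 65 s) is
injected, and

    Z(f) = |F_Vm(f)| / |F_I(f)|

with 100-point moving-average smoothing of both magnitude spectra, cropped
to 1–40 Hz. Each curve is summarized by its resonant frequency f_res and
impedance Z_res, the resonance strength **Q = Z_res/Z₁**, the degree of
high-pass filtering **D = Z₄₀/Z₁**, the resonance quality
**Q/D = Z_res/Z₄₀**, and the −3 dB half-bandwidth HB. A quasi-active
linearization (`zapres.linear_oracle`) provides an exact frequency-domain
solution of the same circuit as an independent cross-check and as a probe
of which conductance *generates* (inductive-like branch) versus
*amplifies* (negative-conductance branch) each resonance.

## Worked example

```python
import zapres as z
from zapres.experiments import SweepPlan, run_input_condition

model = z.build_l5_model(hot_zone=True, resonance_mode=True)
plan, config = SweepPlan(), z.SimConfig()

curve, summary, hold_pA = run_input_condition(
    model, plan.chirp_for("soma"), target_vm=-80.0, config=config)
print(f"hold current {hold_pA:.0f} pA")
print(f"f_res {summary.f_res:.2f} Hz   Z_res {summary.z_res:.1f} MOhm   "
      f"Q/D {summary.quality:.2f}")
```

prints

```
hold current -225 pA
f_res 4.68 Hz   Z_res 61.5 MOhm   Q/D 2.50
```

i.e. with the soma held at −80 mV the somatic input impedance peaks at
about 5 Hz (theta) at ~60 MΩ, a clear band-pass with quality 2.5 —
the h-current/low-threshold-Ca²⁺ resonance of the hyperpolarized
perisomatic membrane. Repeating at −40 mV moves the peak to ~23 Hz
(beta, M-current resonance) with quality ≈ 1 — the high-pass regime.

The same machinery drives the experiment suites (also available from the
`zapres` command line: `input-sweep`, `transfer-sweep`, `hotzone-diff`,
`coincidence`, `dump-kinetics`):

```python
table = z.input_resonance_sweep(model, plan, config)   # tidy DataFrame
diff  = z.hot_zone_difference(model, z.build_l5_model(False, True))
```

## Layout

| module | contents |
| --- | --- |
| `zapres.model_build` | morphology, zones, density maps, hot-zone/resonance switches, morphology file IO |
| `zapres.ion_channels` | Hodgkin–Huxley gate kinetics, the modified g_K(M), calcium pool |
| `zapres.stimulation` | chirp/pulse/EPSP-like waveforms, DC-hold calibration |
| `zapres.simulator` | implicit cable integrator (Hines solve + exponential gates) |
| `zapres.impedance_analysis` | FFT impedance curves, spectral smoothing |
| `zapres.resonance_metrics` | f_res, Z_res, Q, D, Q/D, HB, difference records |
| `zapres.experiments` | input/transfer sweeps, hot-zone difference, coincidence demo |
| `zapres.linear_oracle` | quasi-active linearization, analytic impedance, crosscheck |

All model numbers live in `src/zapres/data/default_model.yaml`; the physics
and parameter choices are documented in `docs/methods.md`.
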