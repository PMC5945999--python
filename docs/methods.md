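# Methods

## Model

The neuron is a reduced, tufted layer 5 pyramidal cell: 20 electrically
distinct cylindrical compartments on a tree — an axon stub (indices 0–1), a
large soma (2, the root), a three-compartment basal cable tapering to a
thin tip (3–5), a tapering apical trunk (6–9), middle apical dendrite
(10–15), distal apical dendrite (16–18) and a thin apical tuft (19). Five
probe sites are used throughout: soma 2, basal 5, middle apical 11, distal
apical 18, tuft 19. All geometry, passive values and channel densities are
data in `src/zapres/data/default_model.yaml`, version-stamped so that every
quantitative result of the package refers to one parameter set.

Passive membrane: axial resistivity 150 Ω·cm; specific capacitance
1 µF/cm² at the soma and axon and 2 µF/cm² in dendrites (the conventional
spine-membrane correction for reduced models of spiny neurons — it is also
what places the dendritic low-pass corner slowly enough for theta-band
resonance); leak reversal −76 mV with region-specific leak densities
(3×10⁻⁵–2.3×10⁻⁴ S/cm²). The resting somatic potential is −68.5 mV; the
distal apical dendrite rests ~6 mV more depolarized because of its dense
h-conductance (E_h = −35 mV).

Eleven conductances in Hodgkin–Huxley form: fast and persistent Na⁺,
delayed-rectifier, A-type, muscarinic (M), Ca²⁺-dependent (C) and
afterhyperpolarization K⁺, low- and high-threshold Ca²⁺, HCN (h) and leak.
Gate steady states are Boltzmann sigmoids and time constants bi-exponential
bells — a parameterized template family in the Traub tradition rather than
a transcription of any particular rate table. Three deliberate
simplifications: Ca²⁺ currents use a fixed +120 mV reversal (ohmic driving
force, adequate subthreshold, rather than GHK), the calcium pool is a
single exponential per compartment (decay 20 ms) feeding g_K(C) and
g_K(AHP) through saturating activation factors, and there is no
temperature/Q10 scaling.

**Modified M current.** The subthreshold variant of g_K(M) applies a
voltage-dependent hyperpolarizing displacement to the activation curve,
s(V) = 15 mV/(1 + exp((V − V_f)/6)) anchored at the foot of the curve
(V_f = v½ − 2k), so the shift approaches 15 mV at hyperpolarized
potentials, decays smoothly with depolarization (<1 mV at +40 mV) and
preserves monotonicity; the time-constant maximum is lowered by exactly
40 ms by uniform scaling. This makes the channel active between rest and
−30 mV, where it generates the depolarized resonance.

**Hot zone.** Compartments 16–19 carry g_Ca(H) at 10× and g_Ca(L) at 100×
the apical-trunk baseline. `apply_hot_zone` defines the multipliers
relative to the baseline (compartment 11), so the operation is idempotent
and `hot_zone=False` reduces the region exactly to the trunk values.

**Resonance mode** zeroes g_Na(F) and g_K(AHP) everywhere and changes
nothing else (bitwise, which the tests verify), so all chirp responses
remain subthreshold.

## Numerics

Voltage is advanced by a Crank–Nicolson (θ = ½) solve of the
tridiagonal-on-tree cable system using Hines elimination (children before
parents); gates use the exponential (Rush–Larsen) update with steady-state
and τ lookup tables on a 0.025 mV grid over [−150, 70] mV, linearly
interpolated. Axial coupling uses the two-half-segment series formula from
cylinder geometry. Default dt = 25 µs, sampling at 10 kHz. Halving dt
changes recorded voltages by well under 0.05 mV on subthreshold protocols
(asserted in the tests). The stepper is numba-compiled; a 67 s simulation
of the full model takes a few seconds on one CPU. There is no randomness
anywhere in the engine: rerunning any suite reproduces its tables
byte-for-byte.

Integration blow-up (|Vm| > 200 mV or non-finite) raises an error carrying
the simulation time. During hold calibration a diverged probe is treated
as an extreme settled potential so the bisection bracket stays consistent.

## Protocols

*Holding.* DC offsets are never hard-coded: `calibrate_hold` bisects the
constant current (bracket ±5 nA, tolerance 0.25 mV, cap 60 iterations)
until the compartment settles at the target after a 2 s DC-only period;
`joint_calibrate` alternates per-compartment bisections until two targets
hold simultaneously. Settled potentials are monotone in the injected
current over the model's subthreshold range, which the tests check.

*Chirp.* I(t) = A·sin(2π[f₀t + (f₁−f₀)t²/(2T)]), 0→40 Hz over 65 s,
starting after the settle period. Amplitudes follow the standard
per-compartment protocol (10 pA basal, 50 pA tuft, 75 pA soma, 100 pA
middle apical, 115 pA distal apical), keeping oscillations near or below
~8 mV peak-to-peak (the tuned model's somatic sweep reaches 8.5 mV pp at
rest, slightly above the nominal envelope).

*Impedance.* Both the voltage and current records over the full 65 s epoch
are mean-subtracted (excluding the DC hold from Z), transformed with an
unpadded FFT, and their magnitude spectra smoothed with a centered
100-point moving average (≈1.5 Hz at the 1/65 Hz resolution; edge windows
shrink) before division; the curve is cropped to 1–40 Hz against
finite-window boundary effects. Smoothing-then-dividing is the default;
divide-then-smooth is available as a sensitivity switch. No taper is
applied — the crop is the boundary mitigation.

*Metrics.* f_res is the argmax (ties to the lowest frequency), Q = Z_res/Z₁,
D = Z₄₀/Z₁, quality Q/D = Z_res/Z₄₀ (an exact identity on every curve), HB
is the width of the contiguous band around f_res with |Z| ≥ Z_res/√2
(−3 dB; a half-height-above-Z₁ alternative is config-exposed). A curve is
flagged resonant iff its maximum is interior and Q > 1.02; the 2% ripple
guard absorbs smoothing noise.

## Quasi-active oracle

Linearizing each current I = ḡΠxᵢ^pᵢ(V−E) around an operating point gives
per gate a branch of weight w = ḡ·(∂Π/∂x)·x∞′(V₀)·(V₀−E) relaxing with
τ(V₀): w > 0 is inductive-like (resonance generator), w < 0 capacitive-like
(amplifier). The tree impedance of this circuit is solved exactly per
frequency. The Ca²⁺ dependence of g_K(C)/g_K(AHP) is frozen at the settled
pool value — a first-order-in-voltage-only limitation. At 10 pA chirp
amplitude the FFT pipeline and the oracle agree within 5% (within ~1% on
passive trees); at 500 pA they visibly diverge, which is reported, not an
error. Dropping all branches of one channel shows whether it generates or
amplifies: h-branch removal collapses the −80 mV somatic resonance,
M-branch removal the −45 mV one, and removing the g_Ca(H) amplifier
branches at −20 mV deflates the distal Z_res (by >30%) while letting the
residual peak drift toward the bare M-current corner.

## Parameter provenance and tuning

The morphology dimensions and densities were calibrated, within the single
parameter file, until the model's chirp pipeline reproduces the documented
resonance phenomenology of the tufted L5 cell: somatic input resonance
running 5 Hz (−80 mV) to 23.5 Hz (−40 mV) and collapsing to quality ≈ 1 by
−35 mV; soma↔distal transfer resonance at ~7.5 Hz with both sites at
−80 mV and ~15 Hz at −55 mV; a ~23% drop of distal resonance quality at
−20 mV when the hot zone is removed (the g_Ca(H) amplification of the
M-resonance, maximal where the g_Ca(H) activation slope and its 2.1 ms τ
maximum sit, at −20 mV); distal resonant impedance peaking near 60 MΩ at
near-rest/moderately depolarized holds; basal Z_res ≈ 600 MΩ, the largest
anywhere; and the four-zone signature (weakly resonant basal, strongly
hyperpolarized-resonant perisomatic region, depolarization-preferring
distal apical, flat tuft). The calibration used the quasi-active oracle
for fast iteration and the full nonlinear chirp pipeline for verification.

## Known limitations

* **Coincidence detection is incomplete.** In spiking mode the 3 nA/5 ms
  somatic step evokes a spike + spikelet whose back-propagation, combined
  with the 1 nA EPSP-like distal input (alpha function, τ = 2 ms, 5 ms
  delay), triggers a visibly broader distal depolarization only when the
  hot zone is present (half-width roughly doubles; a ~10 ms Ca²⁺-boosted
  plateau appears). However, the distal→soma transfer impedance of this
  reduction (~5–6 MΩ) is several-fold weaker than in a full L5
  morphology, so the plateau delivers only ~1 mV of somatic differential
  and the additional somatic action potential does not occur. The
  corresponding acceptance test fails by design rather than being
  weakened; closing the gap requires a coupling-dominated re-reduction of
  the morphology that conflicts with the subthreshold calibration above.
* The distal Z_res hold-profile peaks at −55/−60 mV rather than −45 mV
  (the h/Ca_L and K_M/Ca_H humps do not merge exactly where intended).
* Basal input resonance is frequency-tracked to the somatic h-resonance
  (~4–6 Hz) rather than sweeping 8.5–29 Hz.
* Single cell only; no synaptic background, no stochastic gating, no GHK
  Ca²⁺ driving force, no temperature dependence.

What the synthetic protocols do *not* emulate about experiments: recording
noise, electrode access resistance, imperfect space clamp and biological
variability — passing tests show internal consistency of the model and
pipeline, not agreement with any particular recorded neuron.
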