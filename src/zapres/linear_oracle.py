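"""Quasi-active linearization: a closed-form oracle for the chirp pipeline.

Expanding each Hodgkin–Huxley current I = ḡ·Πxᵢ^pᵢ·(V−E) to first order
around an operating point V₀ yields, per gate, a phenomenological branch
with weight

    w = ḡ_eff · (∂Π/∂x_g)|₀ · x∞'(V₀) · (V₀ − E)        [µS]

relaxing with the local time constant τ_g(V₀), plus the instantaneous chord
conductance ḡ_eff·Π|₀.  Branches with w > 0 behave like inductances
(resonance generators); branches with w < 0 are capacitive-like amplifiers.
The membrane admittance per compartment is then

    Y(ω) = jωC + g_ss + Σ_g w_g / (1 + jωτ_g)

and the full tree impedance follows from a complex sparse solve with the
axial Laplacian.  The calcium dependence of g_K(C)/g_K(AHP) is frozen at the
operating point (first-order in voltage only).

This module never touches the FFT pipeline, so it serves as an independent
cross-check (:func:`crosscheck`) and as a mechanism probe: dropping all
branches of one channel shows whether that channel generates or merely
amplifies a resonance.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np

from .impedance_analysis import ImpedanceCurve, compute_impedance
from .ion_channels import CHANNEL_NAMES, gate_steady_state, gate_tau
from .model_build import NeuronModel
from .simulator import SimConfig, run, _compiled
from .stimulation import (ChirpSpec, HoldSpec, StimulusProgram, calibrate_hold,
                          joint_calibrate)

__all__ = ["GateBranch", "LinearizedMembrane", "linearize",
           "analytic_impedance", "crosscheck"]


@dataclass(frozen=True)
class GateBranch:
    compartment: int
    channel: str
    gate: str
    weight_uS: float  # > 0: generator (inductive-like); < 0: amplifier
    tau_ms: float

    @property
    def is_generator(self) -> bool:
        return self.weight_uS > 0


@dataclass
class LinearizedMembrane:
    """First-order equivalent circuit of the model at an operating point."""

    n: int
    parent: np.ndarray
    axial_uS: np.ndarray  # conductance to parent, 0 at root
    cap_nF: np.ndarray
    g_ss_uS: np.ndarray  # total steady (chord) conductance per compartment
    branches: list[GateBranch]
    v_op: np.ndarray  # operating potentials, mV
    holds: dict[int, float] = field(default_factory=dict)
    hold_currents_pA: dict[int, float] = field(default_factory=dict)

    def drop_branches(self, channel: str, sign: str = "both") -> "LinearizedMembrane":
        """Copy without the given channel's branches (gates frozen at x∞).

        ``sign`` restricts removal to ``'generator'`` (w>0) or
        ``'amplifier'`` (w<0) branches.
        """
        def keep(b: GateBranch) -> bool:
            if b.channel != channel:
                return True
            if sign == "both":
                return False
            if sign == "generator":
                return not b.is_generator
            if sign == "amplifier":
                return b.is_generator
            raise ValueError(f"unknown sign {sign!r}")
        out = copy.copy(self)
        out.branches = [b for b in self.branches if keep(b)]
        return out


def _dprod_dx(powers: list[int], xs: list[float], k: int) -> float:
    out = 1.0
    for j, (p, x) in enumerate(zip(powers, xs)):
        if j == k:
            out *= p * x ** (p - 1) if p >= 1 else 0.0
        else:
            out *= x ** p
    return out


def _solve_holds(model: NeuronModel, holds: dict[int, float],
                 config: SimConfig) -> dict[int, float]:
    """Holding currents (nA) for an arbitrary set of target potentials."""
    if not holds:
        return {}
    items = sorted(holds.items())
    if len(items) == 1:
        comp, vm = items[0]
        return {comp: calibrate_hold(model, HoldSpec(comp, vm), config) * 1e-3}
    if len(items) == 2:
        (ca_, va), (cb, vb) = items
        ia, ib = joint_calibrate(model, HoldSpec(ca_, va), HoldSpec(cb, vb), config)
        return {ca_: ia * 1e-3, cb: ib * 1e-3}
    # general case: alternating single-compartment refinement
    currents = {c: 0.0 for c, _ in items}
    for _ in range(12):
        converged = True
        for comp, vm in items:
            extra = {c: i for c, i in currents.items() if c != comp}
            new = calibrate_hold(model, HoldSpec(comp, vm), config,
                                 extra_dc=extra) * 1e-3
            if abs(new - currents[comp]) > 1e-4:
                converged = False
            currents[comp] = new
        if converged:
            return currents
    return currents


def linearize(model: NeuronModel, holds: dict[int, float] | None = None,
              config: SimConfig | None = None) -> LinearizedMembrane:
    """Quasi-active expansion of the model around a holding condition.

    ``holds`` maps compartments to target potentials (mV); holding currents
    are solved by calibration, the model is settled under them, and every
    compartment is linearized at its settled potential (held or not).
    """
    holds = dict(holds or {})
    config = config or SimConfig()
    for comp, vm in holds.items():
        if not (-120.0 <= vm <= 40.0):
            raise ValueError(f"hold {vm} mV at compartment {comp} outside "
                             "the kinetics validity range [-120, 40] mV")
    currents = _solve_holds(model, holds, config)
    program = StimulusProgram(duration_ms=config.settle_time * 1e3, dc=currents)
    rec = run(model, program, config, record=[0])
    v0 = rec.final_state["v"]
    ca0 = rec.final_state["ca"]

    cm = _compiled(model)
    g_ss = np.zeros(cm.n)
    branches: list[GateBranch] = []
    dv = 1e-3
    for i in range(cm.n):
        vi = float(v0[i])
        for name in CHANNEL_NAMES:
            spec = model.channels[name]
            gbar = model.density(i, name) * model.compartments[i].area_cm2 * 1e6  # µS
            if gbar == 0.0:
                continue
            xs = [float(gate_steady_state(g, vi)) for g in spec.gates]
            powers = [g.power for g in spec.gates]
            prod = 1.0
            for p, x in zip(powers, xs):
                prod *= x ** p
            scale = 1.0
            if spec.ca_dependent:
                if name == "g_K(C)":
                    scale = min(ca0[i] / model.kc_saturation, 1.0)
                else:  # g_K(AHP): gate frozen at its settled value
                    scale = ca0[i] / (ca0[i] + model.ahp_ca_half)
            e = (model.compartments[i].leak_reversal if name == "leak"
                 else spec.reversal)
            g_ss[i] += gbar * prod * scale
            for k, g in enumerate(spec.gates):
                slope = (float(gate_steady_state(g, vi + dv))
                         - float(gate_steady_state(g, vi - dv))) / (2 * dv)
                w = gbar * scale * _dprod_dx(powers, xs, k) * slope * (vi - e)
                if w != 0.0:
                    branches.append(GateBranch(
                        compartment=i, channel=name, gate=g.name,
                        weight_uS=w, tau_ms=float(gate_tau(g, vi))))
    return LinearizedMembrane(
        n=cm.n, parent=cm.parent.copy(), axial_uS=cm.a_uS.copy(),
        cap_nF=cm.cap_nF.copy(), g_ss_uS=g_ss, branches=branches, v_op=v0,
        holds=holds, hold_currents_pA={c: i * 1e3 for c, i in currents.items()})


def analytic_impedance(lin: LinearizedMembrane, injection: int, recording: int,
                       freqs: np.ndarray) -> ImpedanceCurve:
    """Exact impedance magnitude of the linearized tree (MΩ).

    Solves the complex node system per frequency; valid on (0, 200] Hz.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs > 200.0):
        raise ValueError("frequencies must lie in (0, 200] Hz")
    n = lin.n
    mag = np.empty(freqs.size)
    base = np.zeros((n, n), dtype=complex)
    for i in range(n):
        p = lin.parent[i]
        if p >= 0:
            a = lin.axial_uS[i]
            base[i, i] += a
            base[p, p] += a
            base[i, p] -= a
            base[p, i] -= a
    rhs = np.zeros(n, dtype=complex)
    rhs[injection] = 1.0  # 1 nA
    for k, f in enumerate(freqs):
        # ω in rad/ms so that ωτ[ms] and ωC[nF]/g[µS] are dimensionless
        w = 2e-3 * np.pi * f
        y = base.copy()
        for i in range(n):
            y[i, i] += 1j * w * lin.cap_nF[i] + lin.g_ss_uS[i]
        for b in lin.branches:
            y[b.compartment, b.compartment] += b.weight_uS / (1.0 + 1j * w * b.tau_ms)
        z = np.linalg.solve(y, rhs)
        mag[k] = abs(z[recording])
        if not np.isfinite(mag[k]):
            raise np.linalg.LinAlgError(f"singular node system at {f} Hz")
    return ImpedanceCurve(frequency=freqs, magnitude=mag,
                          injection_compartment=injection,
                          recording_compartment=recording,
                          hold_condition=dict(lin.holds),
                          metadata={"source": "quasi_active_oracle"})


def crosscheck(model: NeuronModel, holds: dict[int, float], injection: int,
               recording: int | None = None, amplitude_pA: float = 10.0,
               config: SimConfig | None = None,
               chirp: ChirpSpec | None = None, tol: float = 0.05) -> dict:
    """Chirp/FFT pipeline vs the quasi-active oracle on [1, 40] Hz.

    Runs both routes under the same holding condition and reports the
    maximum relative deviation of the impedance magnitudes; ``passed`` is
    true below ``tol`` (default 5%).  Large chirp amplitudes leave the
    linear regime and are expected to deviate — that is reported, not an
    error.
    """
    recording = injection if recording is None else recording
    config = config or SimConfig()
    lin = linearize(model, holds, config)
    currents_nA = {c: i * 1e-3 for c, i in lin.hold_currents_pA.items()}
    chirp = chirp or ChirpSpec(amplitude=amplitude_pA, compartment=injection)
    if chirp.compartment != injection or chirp.amplitude != amplitude_pA:
        chirp = _dc_replace(chirp, compartment=injection, amplitude=amplitude_pA)
    settle_ms = config.settle_time * 1e3
    program = StimulusProgram(
        duration_ms=settle_ms + chirp.duration * 1e3,
        dc=currents_nA, chirps=[(chirp, settle_ms)])
    rec = run(model, program, config, record=[recording])
    curve = compute_impedance(rec, injection, recording)
    oracle = analytic_impedance(lin, injection, recording, curve.frequency)
    rel = np.abs(curve.magnitude - oracle.magnitude) / oracle.magnitude
    return {
        "max_rel_deviation": float(np.max(rel)),
        "mean_rel_deviation": float(np.mean(rel)),
        "passed": bool(np.max(rel) < tol),
        "tolerance": tol,
        "holds": dict(holds),
        "injection": injection,
        "recording": recording,
        "amplitude_pA": amplitude_pA,
    }
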