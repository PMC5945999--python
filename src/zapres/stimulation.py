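"""Injected-current programs: chirps, DC holds, pulses, EPSP-like waveforms.

A :class:`StimulusProgram` is an ordered set of components, each bound to a
compartment, rendered onto the integration time grid by the simulator.  DC
holding currents are never hard-coded: :func:`calibrate_hold` and
:func:`joint_calibrate` solve for the constant current that settles a
compartment at a requested membrane potential (deterministic bisection).
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ChirpSpec", "HoldSpec", "PulseSpec", "EPSPLikeSpec",
    "chirp_waveform", "epsp_waveform",
    "StimulusProgram", "CalibrationError",
    "calibrate_hold", "joint_calibrate",
]


@dataclass(frozen=True)
class ChirpSpec:
    """Linear chirp: 0→40 Hz over 65 s at fixed amplitude, by default."""

    f_start: float = 0.0  # Hz
    f_end: float = 40.0  # Hz
    duration: float = 65.0  # s
    amplitude: float = 75.0  # pA
    compartment: int = 2

    def __post_init__(self) -> None:
        if not (0 <= self.f_start < self.f_end):
            raise ValueError("need 0 <= f_start < f_end")
        if self.duration <= 0 or self.amplitude <= 0:
            raise ValueError("duration and amplitude must be > 0")


@dataclass
class HoldSpec:
    """Target membrane potential for a DC holding current."""

    compartment: int
    target_vm: float  # mV
    tolerance: float = 0.25  # mV
    solved_current: float | None = None  # pA, filled by calibration

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass(frozen=True)
class PulseSpec:
    """Square current pulse (defaults: the 3 nA / 5 ms somatic step)."""

    amplitude: float = 3.0  # nA
    onset: float = 0.0  # ms
    duration: float = 5.0  # ms
    compartment: int = 2

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


@dataclass(frozen=True)
class EPSPLikeSpec:
    """Alpha-function current: I(t) = peak·(s/τ)·e^(1−s/τ), s = t − onset.

    Defaults give the distal EPSP-like injection: 1 nA peak arriving 5 ms
    after a reference somatic pulse, 2 ms rise time constant (the waveform
    peaks at onset + rise_tau).
    """

    peak: float = 1.0  # nA
    onset_delay: float = 5.0  # ms relative to a reference pulse
    rise_tau: float = 2.0  # ms
    compartment: int = 18

    def __post_init__(self) -> None:
        if self.peak <= 0 or self.rise_tau <= 0:
            raise ValueError("peak and rise_tau must be > 0")


def chirp_waveform(spec: ChirpSpec, t):
    """Chirp current (pA) at time(s) ``t`` in seconds.

    I(t) = A·sin(2π[f_start·t + (f_end−f_start)·t²/(2·duration)]); the
    instantaneous frequency rises linearly from f_start to f_end.  Outside
    [0, duration] the waveform is silent (0 pA).
    """
    ta = np.asarray(t, dtype=float)
    phase = 2.0 * np.pi * (spec.f_start * ta
                           + (spec.f_end - spec.f_start) * ta ** 2 / (2 * spec.duration))
    out = np.where((ta >= 0) & (ta <= spec.duration),
                   spec.amplitude * np.sin(phase), 0.0)
    return out if out.ndim else float(out)


def epsp_waveform(spec: EPSPLikeSpec, t, reference_onset: float = 0.0):
    """EPSP-like current (nA) at time(s) ``t`` in ms."""
    ta = np.asarray(t, dtype=float)
    s = ta - (reference_onset + spec.onset_delay)
    with np.errstate(over="ignore"):
        out = np.where(s > 0,
                       spec.peak * (s / spec.rise_tau) * np.exp(1.0 - s / spec.rise_tau),
                       0.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------


@dataclass
class StimulusProgram:
    """Per-compartment injected current over a run of ``duration_ms``.

    Components: ``dc`` (compartment → constant nA over the whole run),
    ``chirps`` (ChirpSpec, onset_ms), ``pulses`` (PulseSpec with absolute
    onset), ``epsps`` (EPSPLikeSpec, reference_onset_ms).
    """

    duration_ms: float
    dc: dict[int, float] = field(default_factory=dict)  # nA
    chirps: list[tuple[ChirpSpec, float]] = field(default_factory=list)
    pulses: list[PulseSpec] = field(default_factory=list)
    epsps: list[tuple[EPSPLikeSpec, float]] = field(default_factory=list)

    def compartments(self) -> set[int]:
        comps = set(self.dc)
        comps.update(c.compartment for c, _ in self.chirps)
        comps.update(p.compartment for p in self.pulses)
        comps.update(e.compartment for e, _ in self.epsps)
        return comps

    def render(self, dt_ms: float, nsteps: int) -> dict[int, np.ndarray]:
        """Current (nA) per stimulated compartment on the dt grid."""
        t_ms = np.arange(nsteps) * dt_ms
        out: dict[int, np.ndarray] = {}

        def buf(comp):
            if comp not in out:
                out[comp] = np.zeros(nsteps)
            return out[comp]

        for comp, amp in self.dc.items():
            buf(comp)[:] += amp
        for spec, onset_ms in self.chirps:
            buf(spec.compartment)[:] += 1e-3 * chirp_waveform(
                spec, (t_ms - onset_ms) * 1e-3)  # pA -> nA
        for p in self.pulses:
            mask = (t_ms >= p.onset) & (t_ms < p.onset + p.duration)
            buf(p.compartment)[mask] += p.amplitude
        for spec, ref_ms in self.epsps:
            buf(spec.compartment)[:] += epsp_waveform(spec, t_ms, ref_ms)
        return out

    def describe(self) -> dict:
        return {
            "duration_ms": self.duration_ms,
            "dc_nA": {int(k): float(v) for k, v in self.dc.items()},
            "chirps": [{"f_start": c.f_start, "f_end": c.f_end,
                        "duration_s": c.duration, "amplitude_pA": c.amplitude,
                        "compartment": c.compartment, "onset_ms": onset}
                       for c, onset in self.chirps],
            "pulses": [{"amplitude_nA": p.amplitude, "onset_ms": p.onset,
                        "duration_ms": p.duration, "compartment": p.compartment}
                       for p in self.pulses],
            "epsps": [{"peak_nA": e.peak, "onset_delay_ms": e.onset_delay,
                       "rise_tau_ms": e.rise_tau, "compartment": e.compartment,
                       "reference_onset_ms": ref}
                      for e, ref in self.epsps],
        }


class CalibrationError(RuntimeError):
    """Holding-current calibration could not reach the target potential."""


def _settled_vm(model, dc: dict[int, float], comps: list[int], config) -> dict[int, float]:
    from .simulator import run, SimConfig
    config = config or SimConfig()
    program = StimulusProgram(duration_ms=config.settle_time * 1e3, dc=dict(dc))
    rec = run(model, program, config, record=list(comps))
    return {c: float(rec.vm[c][-1]) for c in comps}


def calibrate_hold(model, spec: HoldSpec, config=None, *,
                   bracket_nA: float = 5.0, max_iter: int = 60,
                   extra_dc: dict[int, float] | None = None) -> float:
    """Solve for the DC current (pA) that settles a compartment at target_vm.

    Deterministic bisection over [−bracket, +bracket] nA: the settled
    potential after the configured settle period is monotone in the injected
    current over the subthreshold operating range.  ``extra_dc`` holds fixed
    currents (nA) in other compartments during the search.
    """
    if not (-100.0 <= spec.target_vm <= 10.0):
        raise ValueError("hold target must lie within [-100, +10] mV")
    comp = spec.compartment
    base = dict(extra_dc or {})

    def vm_at(i_nA: float) -> float:
        from .simulator import IntegrationError
        dc = dict(base)
        dc[comp] = dc.get(comp, 0.0) + i_nA
        try:
            return _settled_vm(model, dc, [comp], config)[comp]
        except IntegrationError:
            # a diverged probe acts as an extreme settled potential, keeping
            # the bisection bracket consistent (Vm is monotone in current)
            return math.copysign(1e6, i_nA) if i_nA else 0.0

    lo, hi = -bracket_nA, bracket_nA
    v_mid = vm_at(0.0)
    if abs(v_mid - spec.target_vm) <= spec.tolerance:
        spec.solved_current = 0.0
        return 0.0
    v_lo, v_hi = vm_at(lo), vm_at(hi)
    if not (min(v_lo, v_hi) <= spec.target_vm <= max(v_lo, v_hi)):
        raise CalibrationError(
            f"target {spec.target_vm} mV at compartment {comp} outside the "
            f"±{bracket_nA} nA bracket (settled range "
            f"[{min(v_lo, v_hi):.1f}, {max(v_lo, v_hi):.1f}] mV)")
    increasing = v_hi >= v_lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        v = vm_at(mid)
        if abs(v - spec.target_vm) <= spec.tolerance:
            spec.solved_current = mid * 1e3
            return mid * 1e3
        if (v < spec.target_vm) == increasing:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"calibration for compartment {comp} target {spec.target_vm} mV "
        f"did not converge in {max_iter} iterations")


def joint_calibrate(model, spec_a: HoldSpec, spec_b: HoldSpec, config=None, *,
                    max_sweeps: int = 10, **kwargs) -> tuple[float, float]:
    """Calibrate two holds simultaneously (pA, pA).

    Alternating per-compartment bisection: each sweep re-solves one hold with
    the other's current fixed, until both settled potentials are within
    tolerance at the same time.
    """
    if spec_a.compartment == spec_b.compartment:
        raise ValueError("joint calibration requires two distinct compartments")
    ia = ib = 0.0  # nA
    for _ in range(max_sweeps):
        vs = _settled_vm(model, {spec_a.compartment: ia, spec_b.compartment: ib},
                         [spec_a.compartment, spec_b.compartment], config)
        ok_a = abs(vs[spec_a.compartment] - spec_a.target_vm) <= spec_a.tolerance
        ok_b = abs(vs[spec_b.compartment] - spec_b.target_vm) <= spec_b.tolerance
        if ok_a and ok_b:
            spec_a.solved_current, spec_b.solved_current = ia * 1e3, ib * 1e3
            return ia * 1e3, ib * 1e3
        if not ok_a:
            ia = calibrate_hold(model, replace_hold(spec_a), config,
                                extra_dc={spec_b.compartment: ib}, **kwargs) * 1e-3
        if not ok_b:
            ib = calibrate_hold(model, replace_hold(spec_b), config,
                                extra_dc={spec_a.compartment: ia}, **kwargs) * 1e-3
    raise CalibrationError(
        f"joint calibration ({spec_a.compartment}→{spec_a.target_vm} mV, "
        f"{spec_b.compartment}→{spec_b.target_vm} mV) did not converge "
        f"in {max_sweeps} sweeps")


def replace_hold(spec: HoldSpec) -> HoldSpec:
    return HoldSpec(compartment=spec.compartment, target_vm=spec.target_vm,
                    tolerance=spec.tolerance)
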