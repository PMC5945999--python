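"""Hodgkin–Huxley-style gating kinetics for the reduced L5 pyramidal model.

Every conductance is described by a :class:`ChannelSpec` holding one or two
:class:`GateSpec` gates.  Gate steady states are Boltzmann sigmoids and time
constants are bi-exponential "bell" curves; both are parameterized in the
default parameter file so the whole kinetic scheme is data, not code.

The muscarinic K+ channel (``g_K(M)``) supports a voltage-dependent
hyperpolarizing shift of its activation curve plus a reduction of its time
constant maximum — the subthreshold-resonance variant of the channel.  See
:func:`build_modified_KM`.

Sign convention: :func:`channel_current` returns outward current as positive,
in mA/cm² for ``gbar`` in S/cm² and voltages in mV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GateSpec",
    "ChannelSpec",
    "CalciumPool",
    "gate_steady_state",
    "gate_tau",
    "build_modified_KM",
    "channel_current",
    "CHANNEL_NAMES",
]

#: Canonical channel complement of the model.
CHANNEL_NAMES = (
    "leak",
    "g_Na(F)",
    "g_Na(P)",
    "g_K(DR)",
    "g_K(A)",
    "g_K(M)",
    "g_K(C)",
    "g_K(AHP)",
    "g_Ca(L)",
    "g_Ca(H)",
    "g_h",
)


@dataclass(frozen=True)
class GateSpec:
    """One Hodgkin–Huxley gating variable.

    ``kind`` encodes the monotone direction of the steady-state curve:
    ``activation`` gates open with depolarization (non-decreasing x∞),
    ``inactivation`` gates close with depolarization (non-increasing x∞).
    The HCN gate is therefore of ``inactivation`` kind even though it is the
    channel's opening gate.

    The steady state is a Boltzmann sigmoid
    ``x∞(V) = 1 / (1 + exp(-(V' - v_half)/slope))`` with ``slope > 0`` for
    activation and ``slope < 0`` for inactivation, evaluated at the
    (optionally shifted) voltage ``V' = V + s(V)`` where
    ``s(V) = shift_amp / (1 + exp((V - shift_v_half)/shift_slope))`` — a
    smooth hyperpolarizing displacement that is largest near the foot of the
    curve and vanishes at depolarized potentials.  ``shift_amp = 0`` disables
    the shift.

    The time constant (ms) is
    ``tau(V) = tau_scale * (tau_base + tau_amp /
    (exp((V - tau_v_peak)/tau_sigma) + exp(-(V - tau_v_peak)/tau_sigma)))``,
    a bell with maximum ``tau_scale*(tau_base + tau_amp/2)`` at ``tau_v_peak``.
    """

    name: str
    power: int
    kind: str  # "activation" | "inactivation"
    v_half: float  # mV
    slope: float  # mV; >0 activation, <0 inactivation
    tau_base: float  # ms
    tau_amp: float  # ms
    tau_v_peak: float  # mV
    tau_sigma: float  # mV
    tau_scale: float = 1.0
    shift_amp: float = 0.0  # mV, hyperpolarizing shift amplitude
    shift_v_half: float = -60.0  # mV
    shift_slope: float = 8.0  # mV

    def __post_init__(self) -> None:
        if self.power < 0:
            raise ValueError(f"gate {self.name}: power must be >= 0")
        if self.kind not in ("activation", "inactivation"):
            raise ValueError(f"gate {self.name}: unknown kind {self.kind!r}")
        if (self.kind == "activation") != (self.slope > 0):
            raise ValueError(
                f"gate {self.name}: slope sign must match kind "
                f"(got slope={self.slope} for {self.kind})"
            )
        # |ds/dV| <= shift_amp / (4*shift_slope) must stay below 1 so that
        # V + s(V) remains increasing and monotonicity is preserved.
        if self.shift_amp < 0 or self.shift_slope <= 0:
            raise ValueError(f"gate {self.name}: invalid shift parameters")
        if self.shift_amp / (4.0 * self.shift_slope) >= 1.0:
            raise ValueError(
                f"gate {self.name}: shift too steep (breaks monotonicity)"
            )


@dataclass(frozen=True)
class ChannelSpec:
    """A conductance: named gates, reversal potential, Ca²⁺ dependence.

    ``ca_dependent`` channels (g_K(C), g_K(AHP)) scale their open conductance
    by a saturating function of the local calcium-pool concentration; the
    voltage gates (if any) are handled like any other channel.
    """

    name: str
    gates: tuple[GateSpec, ...]
    reversal: float  # mV
    ca_dependent: bool = False

    def gate(self, gate_name: str) -> GateSpec:
        for g in self.gates:
            if g.name == gate_name:
                return g
        raise KeyError(f"channel {self.name} has no gate {gate_name!r}")


@dataclass
class CalciumPool:
    """First-order per-compartment calcium pool (arbitrary concentration units).

    d[Ca]/dt = influx_scale * I_Ca,inward − [Ca]/decay_tau; with zero influx
    the concentration returns exponentially to baseline 0.
    """

    influx_scale: float  # units per nA·ms
    decay_tau: float  # ms
    concentration: float = 0.0

    def __post_init__(self) -> None:
        if self.decay_tau <= 0:
            raise ValueError("calcium pool decay_tau must be > 0")
        if self.concentration < 0:
            raise ValueError("calcium concentration must be >= 0")


def _shift(gate: GateSpec, v: np.ndarray | float) -> np.ndarray | float:
    if gate.shift_amp == 0.0:
        return 0.0
    return gate.shift_amp / (
        1.0 + np.exp((np.asarray(v, float) - gate.shift_v_half) / gate.shift_slope)
    )


def gate_steady_state(gate: GateSpec, v: np.ndarray | float):
    """Steady-state open fraction x∞(V) ∈ [0, 1]; accepts scalars or arrays."""
    va = np.asarray(v, dtype=float) + _shift(gate, v)
    out = 1.0 / (1.0 + np.exp(-(va - gate.v_half) / gate.slope))
    return out if out.ndim else float(out)


def gate_tau(gate: GateSpec, v: np.ndarray | float):
    """Voltage-dependent relaxation time constant (ms), strictly positive."""
    va = np.asarray(v, dtype=float)
    x = (va - gate.tau_v_peak) / gate.tau_sigma
    out = gate.tau_scale * (gate.tau_base + gate.tau_amp / (np.exp(x) + np.exp(-x)))
    return out if out.ndim else float(out)


def tau_maximum(gate: GateSpec, vmin: float = -120.0, vmax: float = 40.0,
                dv: float = 0.01) -> tuple[float, float]:
    """(argmax voltage, maximum value) of gate_tau on a fine grid."""
    grid = np.arange(vmin, vmax + dv, dv)
    taus = gate_tau(gate, grid)
    i = int(np.argmax(taus))
    return float(grid[i]), float(taus[i])


def build_modified_KM(base: ChannelSpec, max_shift: float = 15.0,
                      tau_reduction: float = 40.0) -> ChannelSpec:
    """Subthreshold variant of g_K(M).

    The activation curve is displaced up to ``max_shift`` mV in the
    hyperpolarizing direction near its foot (the shift decays smoothly to
    zero with depolarization, so the modified steady state is everywhere
    ≥ the base one), and the time-constant maximum is lowered by exactly
    ``tau_reduction`` ms via uniform scaling.
    """
    if base.name != "g_K(M)":
        raise ValueError(f"build_modified_KM applies to g_K(M), got {base.name!r}")
    if max_shift < 0 or tau_reduction < 0:
        raise ValueError("max_shift and tau_reduction must be >= 0")
    m = base.gates[0]
    if max_shift > 0.0:
        # Anchor the shift midpoint at the foot of the activation curve
        # (two slope-widths below half-activation) with a width wide enough
        # to keep V + s(V) monotone.
        shift_v_half = m.v_half - 2.0 * m.slope
        shift_slope = max(max_shift / 3.0, 6.0)
        m = replace(m, shift_amp=max_shift, shift_v_half=shift_v_half,
                    shift_slope=shift_slope)
    if tau_reduction > 0.0:
        _, tmax = tau_maximum(m)
        if tau_reduction >= tmax:
            raise ValueError("tau_reduction exceeds the base tau maximum")
        m = replace(m, tau_scale=m.tau_scale * (tmax - tau_reduction) / tmax)
    return replace(base, gates=(m,) + base.gates[1:])


def ca_scale(ca: float, saturation: float) -> float:
    """Saturating Ca²⁺ activation factor min(ca/saturation, 1)."""
    return min(ca / saturation, 1.0) if saturation > 0 else 1.0


def channel_current(spec: ChannelSpec, gbar: float, v: float,
                    gate_states=(), ca: float = 0.0,
                    ca_saturation: float = 250.0) -> float:
    """Membrane current density (mA/cm², outward positive).

    ``gate_states`` supplies one open fraction per gate in ``spec.gates``
    order; each is raised to its gate's power.  Ca²⁺-dependent channels are
    additionally scaled by ``min(ca/ca_saturation, 1)``.
    """
    g = gbar
    for gate, x in zip(spec.gates, gate_states):
        if not (0.0 <= x <= 1.0):
            raise ValueError(f"gate state {x} outside [0, 1]")
        g *= x ** gate.power
    if spec.ca_dependent:
        g *= ca_scale(ca, ca_saturation)
    return g * (v - spec.reversal)


def channels_from_params(params: dict) -> dict[str, ChannelSpec]:
    """Build the full channel registry from the parameter-file dictionary."""
    reversals = params["reversals"]
    specs: dict[str, ChannelSpec] = {}
    for name, cdef in params["channels"].items():
        gates = []
        for gdef in cdef.get("gates", []):
            tau = gdef["tau"]
            gates.append(GateSpec(
                name=gdef["name"], power=int(gdef["power"]), kind=gdef["kind"],
                v_half=float(gdef["v_half"]), slope=float(gdef["slope"]),
                tau_base=float(tau["base"]), tau_amp=float(tau["amp"]),
                tau_v_peak=float(tau["v_peak"]), tau_sigma=float(tau["sigma"]),
            ))
        rev = cdef["reversal"]
        rev = float(reversals[rev]) if isinstance(rev, str) else float(rev)
        specs[name] = ChannelSpec(
            name=name, gates=tuple(gates), reversal=rev,
            ca_dependent=bool(cdef.get("ca_dependent", False)),
        )
    missing = set(CHANNEL_NAMES) - set(specs)
    if missing:
        raise ValueError(f"parameter file missing channels: {sorted(missing)}")
    return specs
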