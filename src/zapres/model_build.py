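"""Construction of the reduced layer 5 pyramidal neuron model.

The model is a ~20-compartment equivalent-cylinder reduction of a tufted,
regular-spiking L5 pyramidal cell: an axon stub (compartments 0–1), soma (2),
a three-compartment basal cable (3–5), a tapering apical trunk (6–15), distal
apical dendrite (16–18) and apical tuft (19).  Zone labels mark the five
probe sites used throughout the analysis: soma=2, basal=5, middle apical=11,
distal apical=18, tuft=19.

Two switches control the physiological configuration:

* ``hot_zone`` — when on, the distal apical compartments 16–19 carry
  high-threshold Ca²⁺ conductance at 10× and low-threshold Ca²⁺ conductance
  at 100× the apical-trunk baseline, the configuration that supports distal
  Ca²⁺ spikes and strong perisomatic–distal coupling.
* ``resonance_mode`` — when on, the fast Na⁺ and Ca²⁺-dependent AHP K⁺
  conductances are removed everywhere so that all responses stay
  subthreshold, as required for impedance analysis.

All numbers live in ``data/default_model.yaml`` shipped with the package.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .ion_channels import CHANNEL_NAMES, ChannelSpec, build_modified_KM, channels_from_params

__all__ = [
    "ZONES",
    "PROBE_COMPARTMENTS",
    "HOT_ZONE_COMPARTMENTS",
    "CompartmentSpec",
    "NeuronModel",
    "ParameterFileError",
    "MorphologyError",
    "load_default_params",
    "build_l5_model",
    "apply_hot_zone",
    "read_morphology",
    "write_morphology",
]

ZONES = ("soma", "basal", "oblique", "apical_trunk", "middle_apical",
         "distal_apical", "tuft", "axon")

#: Named probe sites (zone -> compartment index).
PROBE_COMPARTMENTS = {
    "soma": 2,
    "basal": 5,
    "middle_apical": 11,
    "distal_apical": 18,
    "tuft": 19,
}

#: Distal apical dendrite (16–18) plus apical tuft (19).
HOT_ZONE_COMPARTMENTS = (16, 17, 18, 19)

#: Apical-trunk compartment whose Ca²⁺ densities define the hot-zone baseline.
_APICAL_BASELINE_COMPARTMENT = 11

_REMOVED_IN_RESONANCE_MODE = ("g_Na(F)", "g_K(AHP)")


class ParameterFileError(RuntimeError):
    """Raised when the structured parameter file cannot be interpreted."""


class MorphologyError(ValueError):
    """Raised on malformed morphology tables (cycles, duplicates, bad rows)."""


@dataclass(frozen=True)
class CompartmentSpec:
    """Geometry, passive membrane and zone label of one compartment."""

    index: int
    parent: int | None
    length: float  # µm
    diameter: float  # µm
    axial_resistivity: float  # Ω·cm
    specific_capacitance: float  # µF/cm²
    leak_conductance_density: float  # S/cm²
    leak_reversal: float  # mV
    zone: str

    def __post_init__(self) -> None:
        if self.zone not in ZONES:
            raise ValueError(f"compartment {self.index}: unknown zone {self.zone!r}")
        for name in ("length", "diameter", "axial_resistivity",
                     "specific_capacitance", "leak_conductance_density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"compartment {self.index}: {name} must be > 0")

    @property
    def area_cm2(self) -> float:
        """Lateral cylinder area in cm² (1 µm² = 1e-8 cm²)."""
        import math
        return math.pi * self.diameter * self.length * 1e-8


@dataclass
class NeuronModel:
    """Compartment tree plus channel densities and configuration flags."""

    compartments: list[CompartmentSpec]
    densities: dict[tuple[int, str], float]  # (compartment, channel) -> S/cm²
    channels: dict[str, ChannelSpec]
    hot_zone: bool
    resonance_mode: bool
    calcium_influx_scale: dict[int, float]  # per-compartment, units/(nA·ms)
    calcium_decay_tau: float  # ms
    kc_saturation: float
    ahp_ca_half: float
    ahp_tau: float  # ms
    ca_multipliers: tuple[float, float] = (10.0, 100.0)  # (g_Ca(H), g_Ca(L))
    params_version: str = "1"

    @property
    def n(self) -> int:
        return len(self.compartments)

    def density(self, index: int, channel: str) -> float:
        return self.densities.get((index, channel), 0.0)

    def zone_of(self, index: int) -> str:
        return self.compartments[index].zone

    def validate(self) -> None:
        _validate_tree(self.compartments)
        for (i, ch), g in self.densities.items():
            if g < 0:
                raise ValueError(f"negative density for {ch} at compartment {i}")
            if ch not in self.channels:
                raise ValueError(f"density refers to unknown channel {ch!r}")
        if self.resonance_mode:
            for (i, ch), g in self.densities.items():
                if ch in _REMOVED_IN_RESONANCE_MODE and g != 0.0:
                    raise ValueError(
                        f"resonance mode requires {ch} = 0 (compartment {i})")
        base_h = self.density(_APICAL_BASELINE_COMPARTMENT, "g_Ca(H)")
        base_l = self.density(_APICAL_BASELINE_COMPARTMENT, "g_Ca(L)")
        mh, ml = (self.ca_multipliers if self.hot_zone else (1.0, 1.0))
        for i in HOT_ZONE_COMPARTMENTS:
            for ch, expected in (("g_Ca(H)", mh * base_h), ("g_Ca(L)", ml * base_l)):
                got = self.density(i, ch)
                if abs(got - expected) > 1e-15 + 1e-9 * abs(expected):
                    raise ValueError(
                        f"hot-zone invariant violated: {ch} at {i} is {got}, "
                        f"expected {expected}")


def _validate_tree(compartments: list[CompartmentSpec]) -> None:
    by_index: dict[int, CompartmentSpec] = {}
    for c in compartments:
        if c.index in by_index:
            raise MorphologyError(f"duplicate compartment index {c.index}")
        by_index[c.index] = c
    roots = [c for c in compartments if c.parent is None]
    if len(roots) != 1:
        raise MorphologyError(f"expected exactly one root, found {len(roots)}")
    for c in compartments:
        if c.parent is not None and c.parent not in by_index:
            raise MorphologyError(
                f"compartment {c.index} references missing parent {c.parent}")
    # cycle check by walking to the root from every node
    for c in compartments:
        seen = set()
        node = c
        while node.parent is not None:
            if node.index in seen:
                raise MorphologyError(f"cycle detected at compartment {c.index}")
            seen.add(node.index)
            node = by_index[node.parent]


_DEFAULT_PARAMS_CACHE: dict | None = None


def load_default_params() -> dict:
    """Load (and cache) the versioned default parameter file."""
    global _DEFAULT_PARAMS_CACHE
    if _DEFAULT_PARAMS_CACHE is None:
        path = Path(__file__).parent / "data" / "default_model.yaml"
        _DEFAULT_PARAMS_CACHE = load_params(path)
    return copy.deepcopy(_DEFAULT_PARAMS_CACHE)


def load_params(path: str | Path) -> dict:
    try:
        with open(path) as fh:
            params = yaml.safe_load(fh)
    except (OSError, yaml.YAMLError) as exc:
        raise ParameterFileError(f"cannot load parameter file {path}: {exc}") from exc
    for section in ("meta", "reversals", "channels", "passive", "morphology",
                    "densities", "calcium", "km_modification", "hot_zone"):
        if section not in params:
            raise ParameterFileError(f"parameter file missing section {section!r}")
    return params


def _resolve_density(densities: dict, channel: str, comp: CompartmentSpec) -> float:
    entry = densities.get(channel)
    if entry is None:
        return 0.0
    if isinstance(entry, (int, float)):
        return float(entry)
    per_comp = entry.get("compartments") or {}
    if comp.index in per_comp:
        return float(per_comp[comp.index])
    zones = entry.get("zones") or {}
    if comp.zone in zones:
        return float(zones[comp.zone])
    return float(entry.get("default", 0.0))


def _compartments_from_params(params: dict) -> list[CompartmentSpec]:
    passive = params["passive"]
    comps = []
    for row in params["morphology"]:
        index, parent, length, diam, zone = (
            int(row["index"]),
            None if row["parent"] is None else int(row["parent"]),
            float(row["length"]), float(row["diameter"]), str(row["zone"]),
        )
        zp = passive.get("zones", {}).get(zone, {})
        comps.append(CompartmentSpec(
            index=index, parent=parent, length=length, diameter=diam, zone=zone,
            axial_resistivity=float(zp.get("axial_resistivity",
                                           passive["axial_resistivity"])),
            specific_capacitance=float(zp.get("specific_capacitance",
                                              passive["specific_capacitance"])),
            leak_conductance_density=float(zp.get("leak_conductance_density",
                                                  passive["leak_conductance_density"])),
            leak_reversal=float(zp.get("leak_reversal", passive["leak_reversal"])),
        ))
    comps.sort(key=lambda c: c.index)
    if [c.index for c in comps] != list(range(len(comps))):
        raise ParameterFileError("compartment indices must be 0..n-1 contiguous")
    _validate_tree(comps)
    return comps


def build_l5_model(hot_zone: bool = True, resonance_mode: bool = True,
                   params: dict | str | Path | None = None) -> NeuronModel:
    """Build the default reduced L5 pyramidal model.

    Parameters
    ----------
    hot_zone
        Apply the distal-apical Ca²⁺ hot zone (g_Ca(H) ×10, g_Ca(L) ×100
        relative to the apical-trunk baseline in compartments 16–19).
    resonance_mode
        Remove g_Na(F) and g_K(AHP) for subthreshold impedance analysis.
    params
        Optional parameter dictionary or path; defaults to the packaged
        parameter file.
    """
    if params is None:
        params = load_default_params()
    elif not isinstance(params, dict):
        params = load_params(params)
    comps = _compartments_from_params(params)
    channels = channels_from_params(params)

    kmmod = params["km_modification"]
    channels["g_K(M)"] = build_modified_KM(
        channels["g_K(M)"],
        max_shift=float(kmmod["max_shift"]),
        tau_reduction=float(kmmod["tau_reduction"]),
    )

    densities: dict[tuple[int, str], float] = {}
    for comp in comps:
        densities[(comp.index, "leak")] = comp.leak_conductance_density
        for ch in CHANNEL_NAMES:
            if ch == "leak":
                continue
            densities[(comp.index, ch)] = _resolve_density(
                params["densities"], ch, comp)

    if resonance_mode:
        for key in list(densities):
            if key[1] in _REMOVED_IN_RESONANCE_MODE:
                densities[key] = 0.0

    hz = params["hot_zone"]
    mult = (float(hz["caH_multiplier"]), float(hz["caL_multiplier"]))

    calc = params["calcium"]
    influx = {}
    for comp in comps:
        # influx scales inversely with membrane area so that a given current
        # density raises small distal compartments faster, as for a thin shell
        influx[comp.index] = float(calc["influx_scale"]) / comp.area_cm2

    model = NeuronModel(
        compartments=comps, densities=densities, channels=channels,
        hot_zone=hot_zone, resonance_mode=resonance_mode,
        calcium_influx_scale=influx,
        calcium_decay_tau=float(calc["decay_tau"]),
        kc_saturation=float(calc["kc_saturation"]),
        ahp_ca_half=float(calc["ahp_ca_half"]),
        ahp_tau=float(calc["ahp_tau"]),
        ca_multipliers=mult,
        params_version=str(params["meta"].get("version", "?")),
    )
    model = apply_hot_zone(model, *(mult if hot_zone else (1.0, 1.0)))
    model.hot_zone = hot_zone
    model.validate()
    return model


def apply_hot_zone(model: NeuronModel, caH_multiplier: float,
                   caL_multiplier: float) -> NeuronModel:
    """Return a copy with hot-zone Ca²⁺ densities scaled relative to the
    apical-trunk baseline.

    Multipliers are absolute with respect to the baseline (compartment 11),
    so the operation is idempotent: applying (10, 100) twice equals once.
    """
    if caH_multiplier < 0 or caL_multiplier < 0:
        raise ValueError("hot-zone multipliers must be >= 0")
    out = copy.deepcopy(model)
    base_h = model.density(_APICAL_BASELINE_COMPARTMENT, "g_Ca(H)")
    base_l = model.density(_APICAL_BASELINE_COMPARTMENT, "g_Ca(L)")
    for i in HOT_ZONE_COMPARTMENTS:
        out.densities[(i, "g_Ca(H)")] = caH_multiplier * base_h
        out.densities[(i, "g_Ca(L)")] = caL_multiplier * base_l
    out.hot_zone = (caH_multiplier, caL_multiplier) == model.ca_multipliers
    return out


# ---------------------------------------------------------------------------
# Tabular morphology dialect: whitespace- or comma-separated, one header line
# ``index parent length diameter zone``; parent is ``-`` (or -1) for the root.

_MORPH_HEADER = ("index", "parent", "length", "diameter", "zone")


def read_morphology(path: str | Path, *, axial_resistivity: float = 200.0,
                    specific_capacitance: float = 1.0,
                    leak_conductance_density: float = 5e-5,
                    leak_reversal: float = -70.0) -> list[CompartmentSpec]:
    """Read a tabular morphology file into compartment specs.

    Passive parameters are not part of the dialect; callers supply them (or
    accept the generic defaults here) — the shipped model instead takes its
    passive values from the parameter file.
    """
    rows = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise MorphologyError(f"{path}: empty morphology file")
    header = tuple(lines[0].replace(",", " ").split())
    if header != _MORPH_HEADER:
        raise MorphologyError(
            f"{path}: expected header {' '.join(_MORPH_HEADER)!r}, got {lines[0]!r}")
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.replace(",", " ").split()
        if len(parts) != 5:
            raise MorphologyError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
        try:
            index = int(parts[0])
            parent = None if parts[1] in ("-", "-1", "none") else int(parts[1])
            length, diameter = float(parts[2]), float(parts[3])
        except ValueError as exc:
            raise MorphologyError(f"{path}:{lineno}: {exc}") from exc
        if parent == index:
            raise MorphologyError(
                f"{path}:{lineno}: compartment {index} is its own parent")
        rows.append(CompartmentSpec(
            index=index, parent=parent, length=length, diameter=diameter,
            zone=parts[4], axial_resistivity=axial_resistivity,
            specific_capacitance=specific_capacitance,
            leak_conductance_density=leak_conductance_density,
            leak_reversal=leak_reversal))
    try:
        _validate_tree(rows)
    except MorphologyError as exc:
        raise MorphologyError(f"{path}: {exc}") from exc
    return sorted(rows, key=lambda c: c.index)


def write_morphology(compartments: list[CompartmentSpec], path: str | Path) -> None:
    """Write the companion tabular format; round-trips with read_morphology."""
    with open(path, "w") as fh:
        fh.write(" ".join(_MORPH_HEADER) + "\n")
        for c in sorted(compartments, key=lambda c: c.index):
            parent = "-" if c.parent is None else str(c.parent)
            fh.write(f"{c.index} {parent} {c.length:g} {c.diameter:g} {c.zone}\n")
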