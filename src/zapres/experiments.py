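"""End-to-end experiment suites.

Four protocols, all built from the lower-level modules:

* :func:`input_resonance_sweep` — per-compartment chirp at a ladder of DC
  holding potentials; local (input) impedance and resonance summary per
  condition.
* :func:`transfer_resonance_sweep` — chirp into one compartment, voltage
  read in another, with the receiving compartment clamped at hyperpolarized
  / resting / depolarized levels by a second DC offset.
* :func:`hot_zone_difference` — both sweeps on the hot-zone and
  hot-zone-removed models under identical plans, emitted as difference rows
  (transfer restricted to near-rest receiving holds).
* :func:`coincidence_demo` — suprathreshold demonstration that the hot zone
  turns coincident somatic + distal input into an extra somatic spike.

All suites are deterministic: identical inputs give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .impedance_analysis import compute_impedance
from .model_build import (HOT_ZONE_COMPARTMENTS, PROBE_COMPARTMENTS,
                          NeuronModel, apply_hot_zone)
from .resonance_metrics import compare_conditions, summarize
from .simulator import SimConfig, detect_spikes, run
from .stimulation import (CalibrationError, ChirpSpec, EPSPLikeSpec, HoldSpec,
                          PulseSpec, StimulusProgram, calibrate_hold,
                          joint_calibrate)

__all__ = ["SweepPlan", "input_resonance_sweep", "transfer_resonance_sweep",
           "hot_zone_difference", "coincidence_demo"]


@dataclass
class SweepPlan:
    """Protocol constants for the resonance sweeps.

    Defaults follow the standard protocol: holds from −80 to −30 mV for
    soma/basal and −80 to 0 mV for apical compartments (5 mV steps for input
    sweeps, 10 mV for transfer sweeps); chirp 0–40 Hz over 65 s with
    per-compartment amplitudes 10 pA (basal), 50 pA (tuft), 75 pA (soma),
    100 pA (middle apical), 115 pA (distal apical); receiving-side holds
    −80/−65/−50 mV at the soma and −75/−60/−30/−3 mV at the distal apical
    dendrite.
    """

    probe_compartments: dict[str, int] = field(
        default_factory=lambda: dict(PROBE_COMPARTMENTS))
    vm_range: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "soma": (-80.0, -30.0), "basal": (-80.0, -30.0),
        "middle_apical": (-80.0, 0.0), "distal_apical": (-80.0, 0.0),
        "tuft": (-80.0, 0.0)})
    vm_step_input: float = 5.0
    vm_step_transfer: float = 10.0
    chirp_amplitude: dict[str, float] = field(default_factory=lambda: {
        "basal": 10.0, "tuft": 50.0, "soma": 75.0,
        "middle_apical": 100.0, "distal_apical": 115.0})
    transfer_holds: dict[str, tuple[float, ...]] = field(default_factory=lambda: {
        "soma": (-80.0, -65.0, -50.0),
        "distal_apical": (-75.0, -60.0, -30.0, -3.0)})
    near_rest_holds: dict[str, float] = field(default_factory=lambda: {
        "soma": -65.0, "distal_apical": -60.0})
    f_start: float = 0.0
    f_end: float = 40.0
    chirp_duration: float = 65.0  # s

    def holds_for(self, zone: str, step: float) -> np.ndarray:
        lo, hi = self.vm_range[zone]
        n = round((hi - lo) / step)
        if abs(lo + n * step - hi) > 1e-9:
            raise ValueError(f"step {step} does not divide range {lo}..{hi}")
        return lo + step * np.arange(n + 1)

    def chirp_for(self, zone: str) -> ChirpSpec:
        return ChirpSpec(f_start=self.f_start, f_end=self.f_end,
                         duration=self.chirp_duration,
                         amplitude=self.chirp_amplitude[zone],
                         compartment=self.probe_compartments[zone])


_SUMMARY_FIELDS = ("f_res", "z_res", "z_1", "z_40", "q", "d", "quality", "hb",
                   "resonant")


def _row_from_summary(s) -> dict:
    return {k: getattr(s, k) for k in _SUMMARY_FIELDS}


def _chirp_program(chirp: ChirpSpec, dc: dict[int, float],
                   config: SimConfig) -> StimulusProgram:
    settle_ms = config.settle_time * 1e3
    return StimulusProgram(duration_ms=settle_ms + chirp.duration * 1e3,
                           dc=dict(dc), chirps=[(chirp, settle_ms)])


def run_input_condition(model: NeuronModel, chirp: ChirpSpec, target_vm: float,
                        config: SimConfig, smoothing_window: int = 100):
    """Calibrate, settle, chirp and summarize one input-impedance condition."""
    comp = chirp.compartment
    hold_pA = calibrate_hold(model, HoldSpec(comp, target_vm), config)
    program = _chirp_program(chirp, {comp: hold_pA * 1e-3}, config)
    rec = run(model, program, config, record=[comp])
    curve = compute_impedance(rec, comp, comp, smoothing_window=smoothing_window)
    curve.hold_condition = {comp: target_vm}
    curve.hot_zone = model.hot_zone
    return curve, summarize(curve), hold_pA


def input_resonance_sweep(model: NeuronModel, plan: SweepPlan | None = None,
                          config: SimConfig | None = None,
                          zones: list[str] | None = None,
                          return_curves: bool = False):
    """Input-resonance table: one row per (probe compartment, hold potential).

    Calibration failures are recorded per condition (``error`` column) and
    the sweep continues.
    """
    if not model.resonance_mode:
        raise ValueError("input resonance sweep requires a resonance-mode model")
    plan = plan or SweepPlan()
    config = config or SimConfig()
    zones = zones or list(plan.probe_compartments)
    rows, curves = [], {}
    for zone in zones:
        comp = plan.probe_compartments[zone]
        chirp = plan.chirp_for(zone)
        for vm in plan.holds_for(zone, plan.vm_step_input):
            row = {"zone": zone, "compartment": comp, "target_vm": float(vm),
                   "hot_zone": model.hot_zone, "error": ""}
            try:
                curve, summ, hold_pA = run_input_condition(model, chirp, vm, config)
                row.update(hold_pA=hold_pA, **_row_from_summary(summ))
                curves[(zone, float(vm))] = curve
            except CalibrationError as exc:
                row["error"] = str(exc)
            rows.append(row)
    df = pd.DataFrame(rows)
    return (df, curves) if return_curves else df


def transfer_resonance_sweep(model: NeuronModel, plan: SweepPlan | None = None,
                             config: SimConfig | None = None,
                             pairs: list[tuple[str, str]] | None = None,
                             transfer_holds: dict[str, tuple[float, ...]] | None = None,
                             return_curves: bool = False):
    """Transfer-resonance table.

    ``pairs`` lists (injection zone, receiving zone); the default covers
    every dendritic probe → soma plus soma → distal apical.  For each pair,
    the injection compartment steps through its hold ladder (10 mV) while
    the receiving compartment is clamped at each of its designated hold
    levels; both holds are solved jointly.
    """
    if not model.resonance_mode:
        raise ValueError("transfer resonance sweep requires a resonance-mode model")
    plan = plan or SweepPlan()
    config = config or SimConfig()
    if pairs is None:
        pairs = [(z, "soma") for z in plan.probe_compartments if z != "soma"]
        pairs.append(("soma", "distal_apical"))
    holds_map = transfer_holds or plan.transfer_holds
    rows, curves = [], {}
    for inj_zone, rec_zone in pairs:
        inj = plan.probe_compartments[inj_zone]
        rcv = plan.probe_compartments[rec_zone]
        chirp = plan.chirp_for(inj_zone)
        rcv_levels = holds_map.get(rec_zone, holds_map.get("soma", (-65.0,)))
        for rcv_vm in rcv_levels:
            for inj_vm in plan.holds_for(inj_zone, plan.vm_step_transfer):
                row = {"injection_zone": inj_zone, "injection": inj,
                       "recording_zone": rec_zone, "recording": rcv,
                       "injection_vm": float(inj_vm), "transfer_vm": float(rcv_vm),
                       "hot_zone": model.hot_zone, "error": ""}
                try:
                    ia, ib = joint_calibrate(model, HoldSpec(inj, inj_vm),
                                             HoldSpec(rcv, rcv_vm), config)
                    program = _chirp_program(
                        chirp, {inj: ia * 1e-3, rcv: ib * 1e-3}, config)
                    rec = run(model, program, config, record=[inj, rcv])
                    curve = compute_impedance(rec, inj, rcv)
                    curve.hold_condition = {inj: float(inj_vm), rcv: float(rcv_vm)}
                    curve.hot_zone = model.hot_zone
                    summ = summarize(curve)
                    row.update(hold_inj_pA=ia, hold_rcv_pA=ib,
                               **_row_from_summary(summ))
                    curves[(inj_zone, rec_zone, float(inj_vm), float(rcv_vm))] = curve
                except CalibrationError as exc:
                    row["error"] = str(exc)
                rows.append(row)
    df = pd.DataFrame(rows)
    return (df, curves) if return_curves else df


def _assert_hot_zone_pair(model_hot: NeuronModel, model_flat: NeuronModel) -> None:
    if not model_hot.hot_zone or model_flat.hot_zone:
        raise ValueError("expected (hot_zone=True, hot_zone=False) models")
    for (key, g) in model_hot.densities.items():
        comp, ch = key
        if comp in HOT_ZONE_COMPARTMENTS and ch in ("g_Ca(H)", "g_Ca(L)"):
            continue
        if abs(model_flat.densities.get(key, 0.0) - g) > 1e-15:
            raise ValueError(f"models differ beyond the hot zone at {key}")


def hot_zone_difference(model_hot: NeuronModel, model_flat: NeuronModel,
                        plan: SweepPlan | None = None,
                        config: SimConfig | None = None,
                        zones: list[str] | None = None,
                        include_transfer: bool = True) -> pd.DataFrame:
    """Difference table (hot-zone-removed relative to hot-zone model).

    Input sweeps run for all probe zones; transfer sweeps only with the
    receiving compartment near rest (soma −65 mV, distal apical −60 mV).
    Negative quality changes mean the hot-zone removal weakened resonance.
    """
    _assert_hot_zone_pair(model_hot, model_flat)
    plan = plan or SweepPlan()
    config = config or SimConfig()
    rows = []

    a = input_resonance_sweep(model_hot, plan, config, zones=zones)
    b = input_resonance_sweep(model_flat, plan, config, zones=zones)
    for (_, ra), (_, rb) in zip(a.iterrows(), b.iterrows()):
        if ra["error"] or rb["error"]:
            continue
        rows.append({
            "kind": "input", "zone": ra["zone"], "compartment": ra["compartment"],
            "target_vm": ra["target_vm"],
            "quality_change_pct": 100.0 * (rb["quality"] - ra["quality"]) / ra["quality"],
            "f_res_change_Hz": rb["f_res"] - ra["f_res"],
            "z_res_change_MOhm": rb["z_res"] - ra["z_res"],
        })

    if include_transfer:
        pairs = [(z, "soma") for z in plan.probe_compartments if z != "soma"]
        pairs.append(("soma", "distal_apical"))
        near = {"soma": (plan.near_rest_holds["soma"],),
                "distal_apical": (plan.near_rest_holds["distal_apical"],)}
        ta = transfer_resonance_sweep(model_hot, plan, config, pairs=pairs,
                                      transfer_holds=near)
        tb = transfer_resonance_sweep(model_flat, plan, config, pairs=pairs,
                                      transfer_holds=near)
        for (_, ra), (_, rb) in zip(ta.iterrows(), tb.iterrows()):
            if ra["error"] or rb["error"]:
                continue
            rows.append({
                "kind": "transfer", "zone": ra["injection_zone"],
                "compartment": ra["injection"], "target_vm": ra["injection_vm"],
                "quality_change_pct": 100.0 * (rb["quality"] - ra["quality"]) / ra["quality"],
                "f_res_change_Hz": rb["f_res"] - ra["f_res"],
                "z_res_change_MOhm": rb["z_res"] - ra["z_res"],
            })
    return pd.DataFrame(rows)


def _halfwidth_ms(time_s: np.ndarray, v: np.ndarray, t0_ms: float) -> float:
    """Full width at half maximum of the depolarization after t0."""
    t_ms = time_s * 1e3
    sel = t_ms >= t0_ms
    t_ms, v = t_ms[sel], v[sel]
    base = v[0]
    peak = float(np.max(v))
    if peak - base < 1.0:
        return 0.0
    level = base + 0.5 * (peak - base)
    above = v >= level
    idx = np.where(above)[0]
    return float(t_ms[idx[-1]] - t_ms[idx[0]])


def coincidence_demo(model: NeuronModel, config: SimConfig | None = None,
                     spike_threshold: float = -10.0) -> dict:
    """Four-scenario coincidence-detection report.

    Scenarios: {hot zone, no hot zone} × {somatic pulse alone, somatic pulse
    + EPSP-like distal input}.  The somatic stimulus is a 3 nA / 5 ms step;
    the distal waveform peaks at 1 nA and is delayed 5 ms relative to the
    step.  Reports somatic spike counts and the half-width of the distal
    apical depolarization per scenario.
    """
    if model.resonance_mode:
        raise ValueError("coincidence demo requires the spiking-mode model "
                         "(g_Na(F) and g_K(AHP) restored)")
    config = config or SimConfig(settle_time=1.0)
    soma = PROBE_COMPARTMENTS["soma"]
    distal = PROBE_COMPARTMENTS["distal_apical"]
    model_hot = model if model.hot_zone else apply_hot_zone(model, *model.ca_multipliers)
    model_flat = apply_hot_zone(model, 1.0, 1.0)

    settle_ms = config.settle_time * 1e3
    window_ms = 300.0
    report: dict[str, dict] = {}
    for label, m in (("hot_zone", model_hot), ("no_hot_zone", model_flat)):
        for distal_input in (False, True):
            pulse = PulseSpec(onset=settle_ms, compartment=soma)
            program = StimulusProgram(duration_ms=settle_ms + window_ms,
                                      pulses=[pulse])
            if distal_input:
                program.epsps.append(
                    (EPSPLikeSpec(compartment=distal), settle_ms))
            rec = run(m, program, config, record=[soma, distal])
            spikes = detect_spikes(rec, soma, threshold=spike_threshold)
            spikes = spikes[spikes >= settle_ms - 1.0]
            key = f"{label}_{'with' if distal_input else 'without'}_distal"
            report[key] = {
                "somatic_spikes": int(spikes.size),
                "spike_times_ms": [float(s - settle_ms) for s in spikes],
                "distal_halfwidth_ms": _halfwidth_ms(
                    rec.time, rec.vm[distal], settle_ms),
            }
    report["extra_spike_with_hot_zone"] = (
        report["hot_zone_with_distal"]["somatic_spikes"]
        - report["hot_zone_without_distal"]["somatic_spikes"])
    report["extra_spike_without_hot_zone"] = (
        report["no_hot_zone_with_distal"]["somatic_spikes"]
        - report["no_hot_zone_without_distal"]["somatic_spikes"])
    return report
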