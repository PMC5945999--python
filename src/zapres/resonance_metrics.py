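"""Resonance quantification of impedance curves.

For a curve |Z(f)| on 1–40 Hz:

* f_res — frequency of the global maximum (ties broken toward the lowest
  frequency); Z_res — the maximum magnitude.
* Q = Z_res / Z_1 (resonance strength), D = Z_40 / Z_1 (degree of high-pass
  filtering), and resonance quality Q/D = Z_res / Z_40 — the dimensionless
  band-pass sharpness metric.  Q/D ≈ 1 flags broadband or high-pass curves
  rather than true resonance.
* HB — half-bandwidth: width of the contiguous band around f_res where
  |Z| ≥ Z_res/√2 (−3 dB), clipped to [1, 40].  A configurable alternative
  uses half height above Z_1.
* ``resonant`` — true iff f_res is interior (not at either grid boundary)
  and Q exceeds 1 by more than a small ripple tolerance (default 0.02).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .impedance_analysis import ImpedanceCurve

__all__ = ["ResonanceSummary", "MetricError", "summarize", "compare_conditions"]

#: Ripple tolerance above Q = 1 for the resonant flag.
RESONANT_EPSILON = 0.02


class MetricError(RuntimeError):
    pass


@dataclass(frozen=True)
class ResonanceSummary:
    f_res: float  # Hz
    z_res: float  # MΩ
    z_1: float  # MΩ
    z_40: float  # MΩ
    q: float  # Z_res / Z_1
    d: float  # Z_40 / Z_1
    quality: float  # Q/D = Z_res / Z_40
    hb: float  # Hz
    resonant: bool


def summarize(curve: ImpedanceCurve, *, epsilon: float = RESONANT_EPSILON,
              hb_mode: str = "sqrt2") -> ResonanceSummary:
    """Compute the resonance summary for one impedance curve."""
    f = np.asarray(curve.frequency, dtype=float)
    z = np.asarray(curve.magnitude, dtype=float)
    if f.size < 3 or np.any(np.diff(f) <= 0):
        raise MetricError("frequency grid must be strictly increasing")
    if not np.all(np.isfinite(z)):
        raise MetricError("non-finite impedance magnitudes")
    if hb_mode not in ("sqrt2", "half_above_z1"):
        raise ValueError(f"unknown hb_mode {hb_mode!r}")

    imax = int(np.argmax(z))  # np.argmax returns the first (lowest-f) maximum
    f_res, z_res = float(f[imax]), float(z[imax])
    z_1 = float(z[int(np.argmin(np.abs(f - 1.0)))])
    z_40 = float(z[int(np.argmin(np.abs(f - 40.0)))])
    q = z_res / z_1
    d = z_40 / z_1
    quality = z_res / z_40

    level = (z_res / math.sqrt(2.0) if hb_mode == "sqrt2"
             else z_1 + 0.5 * (z_res - z_1))
    lo = imax
    while lo > 0 and z[lo - 1] >= level:
        lo -= 1
    hi = imax
    while hi < z.size - 1 and z[hi + 1] >= level:
        hi += 1
    hb = float(f[hi] - f[lo])

    interior = 0 < imax < z.size - 1
    return ResonanceSummary(f_res=f_res, z_res=z_res, z_1=z_1, z_40=z_40,
                            q=q, d=d, quality=quality, hb=hb,
                            resonant=bool(interior and q > 1.0 + epsilon))


def compare_conditions(a: ResonanceSummary, b: ResonanceSummary,
                       *, meta_a: dict | None = None,
                       meta_b: dict | None = None) -> dict:
    """Difference record between two summaries of the same condition.

    ``a`` is the reference (hot-zone) case and ``b`` the comparison
    (hot-zone-removed) case, so decreases come out negative:
    quality change is 100·(b.quality − a.quality)/a.quality (%), f_res and
    Z_res changes are absolute (Hz, MΩ).

    If condition metadata is supplied, the injection/recording pair and hold
    map must match and the hot_zone flag must differ.
    """
    if meta_a is not None and meta_b is not None:
        for key in ("injection_compartment", "recording_compartment",
                    "hold_condition"):
            if meta_a.get(key) != meta_b.get(key):
                raise ValueError(f"mismatched condition field {key!r}")
        if meta_a.get("hot_zone") == meta_b.get("hot_zone"):
            raise ValueError("conditions must differ in the hot_zone flag")
    return {
        "quality_change_pct": 100.0 * (b.quality - a.quality) / a.quality,
        "f_res_change_Hz": b.f_res - a.f_res,
        "z_res_change_MOhm": b.z_res - a.z_res,
        "hb_change_Hz": b.hb - a.hb,
    }
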