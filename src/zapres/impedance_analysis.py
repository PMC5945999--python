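"""Chirp-response → impedance-curve analysis.

The impedance magnitude is |Z(f)| = |F_Vm(f)| / |F_I(f)| over the full chirp
epoch, with both magnitude spectra smoothed by a centered moving average
(default 100 points ≈ 1.5 Hz at the 65 s epoch's 1/65 Hz resolution) before
the ratio is taken, then cropped to 1–40 Hz to avoid finite-window boundary
effects.  Both time series are mean-subtracted over the epoch so the DC
holding current and offset potential do not enter Z.  No taper is applied
before the transform; the crop is the boundary-effect mitigation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulator import Recording

__all__ = ["ImpedanceCurve", "AnalysisError", "compute_impedance", "smooth_spectrum"]

FREQ_BAND = (1.0, 40.0)  # Hz


class AnalysisError(RuntimeError):
    pass


@dataclass
class ImpedanceCurve:
    """|Z(f)| in MΩ on the cropped [1, 40] Hz grid for one condition."""

    frequency: np.ndarray  # Hz, strictly increasing
    magnitude: np.ndarray  # MΩ, >= 0
    injection_compartment: int
    recording_compartment: int
    hold_condition: dict[int, float] = field(default_factory=dict)  # comp -> mV
    hot_zone: bool | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def is_input(self) -> bool:
        return self.injection_compartment == self.recording_compartment

    def scaled(self, factor: float) -> "ImpedanceCurve":
        return ImpedanceCurve(self.frequency.copy(), self.magnitude * factor,
                              self.injection_compartment, self.recording_compartment,
                              dict(self.hold_condition), self.hot_zone,
                              dict(self.metadata))

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({"frequency_Hz": self.frequency,
                             "impedance_MOhm": self.magnitude})

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def smooth_spectrum(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge shrinkage.

    ``window`` is adjusted up to the next odd integer so the average is
    centered; at the edges the window is truncated to the available points
    (so a constant series is unchanged).  ``window=1`` is the identity.
    """
    values = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > values.size:
        raise ValueError(f"window {window} exceeds series length {values.size}")
    if window % 2 == 0:
        window += 1
    if window == 1:
        return values.copy()
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    n = values.size
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def compute_impedance(rec: Recording, injection: int, recording: int,
                      smoothing_window: int = 100,
                      smoothing_mode: str = "spectra") -> ImpedanceCurve:
    """Impedance curve from a chirp recording.

    ``smoothing_mode='spectra'`` (default) smooths the voltage and current
    magnitude spectra separately before dividing; ``'ratio'`` divides first
    and smooths the quotient (sensitivity-check variant).
    """
    chirps = rec.metadata.get("stimulus", {}).get("chirps", [])
    chirp = next((c for c in chirps if c["compartment"] == injection), None)
    if chirp is None:
        raise AnalysisError(
            f"recording metadata has no chirp injected at compartment {injection}")
    if recording not in rec.vm:
        raise AnalysisError(f"compartment {recording} was not recorded")
    if smoothing_mode not in ("spectra", "ratio"):
        raise ValueError(f"unknown smoothing_mode {smoothing_mode!r}")

    t0 = chirp["onset_ms"] * 1e-3
    t1 = t0 + chirp["duration_s"]
    t = rec.time
    if t[-1] + 1e-9 < t1:
        raise AnalysisError("recording does not span the full chirp epoch")
    sel = (t >= t0) & (t < t1)
    v = rec.vm[recording][sel]
    i_nA = rec.injected[injection][sel] * 1e-3  # pA -> nA
    v = v - v.mean()
    i_nA = i_nA - i_nA.mean()

    dt = float(t[1] - t[0])
    freqs = np.fft.rfftfreq(v.size, d=dt)
    fv = np.abs(np.fft.rfft(v))
    fi = np.abs(np.fft.rfft(i_nA))
    if smoothing_mode == "spectra":
        fv = smooth_spectrum(fv, smoothing_window)
        fi = smooth_spectrum(fi, smoothing_window)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = fv / fi
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = fv / fi
        # smooth the ratio on a band wide enough to cover the 1-40 Hz crop
        band = (freqs >= 0.25) & (freqs <= 60.0)
        z[~band] = np.nan
        z[band] = smooth_spectrum(z[band], smoothing_window)

    crop = (freqs >= FREQ_BAND[0]) & (freqs <= FREQ_BAND[1])
    if not np.all(np.isfinite(z[crop])):
        raise AnalysisError("non-finite impedance values inside 1-40 Hz")
    df = float(freqs[1] - freqs[0])
    eff_window = smoothing_window + (smoothing_window % 2 == 0)
    return ImpedanceCurve(
        frequency=freqs[crop], magnitude=z[crop],
        injection_compartment=injection, recording_compartment=recording,
        metadata={
            "frequency_resolution_Hz": df,
            "smoothing_window_points": eff_window,
            "smoothing_span_Hz": eff_window * df,
            "smoothing_mode": smoothing_mode,
            "chirp": dict(chirp),
            "model_hash": rec.metadata.get("model_hash"),
        })
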