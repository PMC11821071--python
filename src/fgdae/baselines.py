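"""Classical zero-phase high-pass filter baselines.

Both filters target baseline wander: a 4th-order Butterworth IIR applied
forward-backward (zero phase, squared magnitude response) and a symmetric
linear-phase FIR applied by centered convolution (zero phase by symmetry),
each with a 0.67 Hz cutoff at 360 Hz.  The FIR is designed as the
complement of a unity-DC windowed lowpass (``delta - h_lp``), so its taps
sum exactly to zero — a constant input is nulled to machine precision —
while the passband gain is 1 minus the lowpass leakage.  The tap count and
window are this package's own design choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, firwin, sosfiltfilt

__all__ = ["FilterSpec", "iir_highpass_denoise", "fir_highpass_denoise"]


@dataclass
class FilterSpec:
    kind: str = "IIR"
    cutoff_hz: float = 0.67
    order: int = 4
    zero_phase: bool = True
    fs: float = 360.0
    fir_taps: int = 1001  # odd; symmetric Hamming-window complement-of-lowpass

    def __post_init__(self):
        if not 0 < self.cutoff_hz < self.fs / 2:
            raise ValueError("cutoff must lie below the Nyquist frequency")
        if self.fir_taps % 2 == 0:
            raise ValueError("fir_taps must be odd for a symmetric zero-phase kernel")


def iir_highpass_denoise(x, spec: FilterSpec = None) -> np.ndarray:
    """Forward-backward Butterworth high-pass; output length equals input."""
    spec = spec or FilterSpec(kind="IIR")
    x = np.asarray(x, dtype=float)
    sos = butter(spec.order, spec.cutoff_hz, btype="highpass", fs=spec.fs, output="sos")
    min_len = 3 * (2 * spec.order + 1)
    if x.shape[-1] <= min_len:
        raise ValueError(f"input too short for zero-phase filtering (need > {min_len} samples)")
    # pad well past the filter's settling time so the edge transients (and
    # with them any forward/backward asymmetry) decay below ~1e-10
    padlen = min(x.shape[-1] - 1, int(10 * spec.fs / spec.cutoff_hz))
    return sosfiltfilt(sos, x, axis=-1, padlen=padlen)


def _fir_kernel(spec: FilterSpec) -> np.ndarray:
    lp = firwin(spec.fir_taps, spec.cutoff_hz, fs=spec.fs, pass_zero=True, window="hamming")
    h = -lp / lp.sum()  # unity-DC lowpass, negated
    h[spec.fir_taps // 2] += 1.0  # delta - lowpass: exact null at DC
    return h


def fir_highpass_denoise(x, spec: FilterSpec = None) -> np.ndarray:
    """Zero-phase FIR high-pass via centered convolution with reflect padding."""
    spec = spec or FilterSpec(kind="FIR")
    x = np.asarray(x, dtype=float)
    h = _fir_kernel(spec)
    half = len(h) // 2
    if x.shape[-1] <= half:
        raise ValueError(f"input too short for the {len(h)}-tap kernel")
    if x.ndim == 1:
        xp = np.pad(x, half, mode="reflect")
        return np.convolve(xp, h, mode="valid")
    return np.stack([fir_highpass_denoise(row, spec) for row in x])
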