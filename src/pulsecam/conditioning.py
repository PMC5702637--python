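"""Shared signal conditioning: centering, inversion, band-pass, derivative.

Applied to the camera ratio signal and to the earlobe PPG channel before beat
detection. The band-pass (0.5-2.0 Hz second-order Butterworth) brackets
plausible heart rates — a healthy resting adult beats at roughly 0.75-1.0 Hz
(60-80 bpm) — and is applied forward-backward by default so the filter adds
no phase delay: beat *timing* is the product, and phase distortion would bias
the interbeat intervals.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .series import UniformSeries

__all__ = [
    "BandpassSpec",
    "center_on_zero",
    "invert_signal",
    "bandpass",
    "first_derivative",
]

# filtered output this close to either end is transient-contaminated and is
# flagged for exclusion from peak detection
TRANSIENT_S = 2.0


@dataclass
class BandpassSpec:
    low_cut: float = 0.5  # Hz
    high_cut: float = 2.0  # Hz
    order: int = 2  # prototype order per edge

    def validate(self, fs: float) -> None:
        if not 0 < self.low_cut < self.high_cut < fs / 2:
            raise ValueError(
                f"need 0 < low_cut < high_cut < fs/2, got "
                f"({self.low_cut}, {self.high_cut}) at fs={fs}"
            )
        if self.order < 1:
            raise ValueError("order must be >= 1")


def center_on_zero(s: UniformSeries) -> UniformSeries:
    """Subtract the first value from the whole trend."""
    if len(s) == 0:
        raise ValueError("empty series")
    return s.with_values(s.values - s.values[0])


def invert_signal(s: UniformSeries) -> UniformSeries:
    """Mean-centered negation: flips the reflectance ratio into a blood-volume
    convention (peaks up). Negation rather than reciprocal: for a ratio near
    2.0 the reciprocal is an affine flip to first order, and negation is
    numerically safe."""
    if len(s) == 0:
        raise ValueError("empty series")
    return s.with_values(np.mean(s.values) - s.values)


def bandpass(s: UniformSeries, spec: BandpassSpec | None = None, zero_phase: bool = True) -> UniformSeries:
    """Butterworth band-pass. ``zero_phase`` applies it forward-backward
    (no group delay; the magnitude response is squared, so each cutoff sits at
    gain 0.5 instead of the single-pass 1/sqrt(2)). A causal single pass is
    available for comparison with online processing."""
    spec = spec or BandpassSpec()
    spec.validate(s.fs)
    sos = signal.butter(
        spec.order, [spec.low_cut, spec.high_cut], btype="bandpass", fs=s.fs, output="sos"
    )
    if zero_phase:
        filtered = signal.sosfiltfilt(sos, s.values)
    else:
        filtered = signal.sosfilt(sos, s.values)
    out = s.with_values(filtered)
    out.edge_exclude_s = max(s.edge_exclude_s, TRANSIENT_S)
    return out


def first_derivative(s: UniformSeries) -> UniformSeries:
    """Central-difference derivative in units per second (one-sided at the
    endpoints). Augments slope changes so pulse arrival is easier to time."""
    if len(s) < 2:
        raise ValueError("need at least 2 samples for a derivative")
    return s.with_values(np.gradient(s.values, 1.0 / s.fs))
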