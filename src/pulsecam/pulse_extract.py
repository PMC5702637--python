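"""Camera frames -> raw arterial pulse signal.

The chain: per-frame ROI color means -> green/red common-mode-rejection ratio
-> interpolation onto a uniform 1 kHz grid -> (conditioning ops) -> the PhyC
pulse channel. Blue is never used: it carries the melanin information that
varies with skin color, while green and red reflectance is dominated by
hemoglobin absorption and so tracks blood volume.
"""
from __future__ import annotations

import numpy as np
from scipy.interpolate import PchipInterpolator

from .series import FrameSequence, IrregularSeries, RoiMask, UniformSeries

__all__ = [
    "FrameSequence",
    "RoiMask",
    "IrregularSeries",
    "UniformSeries",
    "channel_means",
    "green_red_ratio",
    "resample_uniform",
    "video_to_pulse",
]

MAX_FRAME_GAP_S = 0.5  # longer gaps mean the tracker lost the face
_RED_EPS = 1e-9


def channel_means(frames: FrameSequence, roi: RoiMask) -> tuple[IrregularSeries, IrregularSeries, IrregularSeries]:
    """Arithmetic mean of the masked pixels per color plane, per frame.

    Returns (red, green, blue) series on the frame timestamps.
    """
    if roi.mask.shape != frames.frame_shape:
        raise ValueError(
            f"mask shape {roi.mask.shape} does not match frames {frames.frame_shape}"
        )
    # (n_frames, n_roi_pixels, 3) -> per-frame channel means
    means = frames.frames[:, roi.mask, :].mean(axis=1, dtype=float)
    ts = frames.timestamps
    return (
        IrregularSeries(times=ts, values=means[:, 0]),
        IrregularSeries(times=ts, values=means[:, 1]),
        IrregularSeries(times=ts, values=means[:, 2]),
    )


def green_red_ratio(g: IrregularSeries, r: IrregularSeries) -> IrregularSeries:
    """Green/red ratio: cancels illumination and movement components common to
    both channels (multiplying every pixel by a gain g(t) leaves it unchanged)."""
    if len(g) != len(r) or not np.array_equal(g.times, r.times):
        raise ValueError("green and red series must share identical timestamps")
    if np.any(r.values <= _RED_EPS):
        raise ValueError("red channel mean is <= 0; ratio undefined")
    return IrregularSeries(times=g.times, values=g.values / r.values)


def resample_uniform(s: IrregularSeries, fs: float = 1000.0) -> UniformSeries:
    """Interpolate an irregular series onto the uniform grid t0 + k/fs.

    Uses monotone-preserving piecewise-cubic (PCHIP) interpolation: upsampling
    ~60 Hz camera samples to 1 kHz with straight lines leaves spectral kinks
    inside the 0.5-2 Hz heart-rate band. No extrapolation: the grid spans
    [first, last] timestamp only.
    """
    if len(s) < 2:
        raise ValueError("need at least 2 samples to resample")
    span = s.times[-1] - s.times[0]
    if span < 1.0:
        raise ValueError("need at least 1 s of data to resample")
    max_gap = float(np.max(np.diff(s.times)))
    if max_gap > MAX_FRAME_GAP_S:
        raise ValueError(
            f"gap of {max_gap * 1e3:.0f} ms between samples (> {MAX_FRAME_GAP_S * 1e3:.0f} ms): "
            "tracking loss, cannot interpolate across"
        )
    interp = PchipInterpolator(s.times, s.values)
    n = int(np.floor(span * fs)) + 1
    grid = s.times[0] + np.arange(n) / fs
    return UniformSeries(values=interp(grid), fs=fs, t0=float(s.times[0]))


def video_to_pulse(
    frames: FrameSequence,
    roi: RoiMask,
    fs: float = 1000.0,
    band: tuple[float, float] = (0.5, 2.0),
) -> UniformSeries:
    """Full pulse-extraction chain: ROI means -> G/R ratio -> 1 kHz grid ->
    inversion -> 0.5-2 Hz Butterworth band-pass -> first derivative.

    Inversion maps the ratio onto blood volume (more blood, more absorption,
    less reflected light); the derivative augments slope changes to stabilize
    pulse-arrival timing. Output channel_tag is ``phyc``.
    """
    from . import conditioning  # composition of the next stage's ops

    r, g, _ = channel_means(frames, roi)
    ratio = green_red_ratio(g, r)
    uniform = resample_uniform(ratio, fs=fs)
    inverted = conditioning.invert_signal(uniform)
    spec = conditioning.BandpassSpec(low_cut=band[0], high_cut=band[1], order=2)
    filtered = conditioning.bandpass(inverted, spec)
    pulse = conditioning.first_derivative(filtered)
    pulse.channel_tag = "phyc"
    return pulse
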