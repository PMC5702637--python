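"""Ground-truthed synthetic physiology: IBI series, waveforms, video frames.

The generator lays down heartbeats whose interbeat intervals (IBIs) carry the
two oscillatory components the HRV pipeline is built to quantify:

* a respiratory-band modulation (0.12-0.40 Hz) standing in for respiratory
  sinus arrhythmia (RSA), and
* a low-frequency modulation (0.04-0.10 Hz) standing in for baroreceptor /
  vasomotor rhythms (LF),

plus white beat-to-beat noise and an optional linear heart-period drift.
Peripheral pulse arrival is modelled as a delayed, jittered copy of the
cardiac beat train: the vasculature acts as a filter between the electrical
event (ECG R-wave) and the optical pulse at the periphery, and the jitter SD
sets how much beat-level agreement between the two sensors degrades.

Everything is reproducible from ``SynthConfig.seed``; a :class:`GroundTruth`
object carries the quantities recovery tests compare against.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .series import FrameSequence, RoiMask, UniformSeries

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_ibi_series",
    "render_waveform",
    "render_video",
    "add_noise",
    "write_fixture",
]

RSA_BAND = (0.12, 0.40)  # Hz, spontaneous adult breathing
LF_BAND = (0.04, 0.10)  # Hz, baroreceptor / vasomotor band
IBI_BOUNDS_MS = (200.0, 3000.0)  # physiological plausibility bounds


@dataclass
class SynthConfig:
    """Parameters of the simulated subject, camera, and optics.

    Defaults describe a resting adult (heart period 800 ms, i.e. 75 bpm),
    breathing at 0.25 Hz with a 40 ms RSA modulation, a 20 ms vasomotor
    oscillation at 0.08 Hz, and 5 ms of unstructured beat-to-beat noise.
    The pulse reaches the face ~200 ms after the R-wave with ~10 ms of
    transit jitter. The camera runs at ~60 fps with millisecond-scale
    timestamp jitter.
    """

    base_hp: float = 800.0  # ms, mean heart period
    rsa_amp: float = 40.0  # ms, respiratory modulation amplitude
    rsa_freq: float = 0.25  # Hz, within RSA_BAND
    lf_amp: float = 20.0  # ms, low-frequency modulation amplitude
    lf_freq: float = 0.08  # Hz, within LF_BAND
    lf_phase: float = 0.0  # rad
    beat_noise_sd: float = 5.0  # ms, white beat-to-beat noise
    hp_slope: float = 0.0  # ms/s, linear heart-period drift
    duration: float = 300.0  # s
    seed: int = 0
    # vascular transit (cardiac event -> peripheral pulse arrival)
    transit_delay: float = 200.0  # ms
    transit_jitter_sd: float = 10.0  # ms
    # camera
    frame_rate: float = 60.0  # Hz
    frame_ts_jitter_sd: float = 1.0  # ms
    pixel_noise_sd: float = 1.0  # intensity units (8-bit scale)
    illum_drift_amp: float = 3.0  # intensity units at mid-gray
    illum_drift_freq: float = 0.05  # Hz
    modulation_depth_green: float = 3.0  # intensity units
    modulation_depth_red: float = 1.0  # intensity units

    def validate(self) -> None:
        if not 300.0 <= self.base_hp <= 2000.0:
            raise ValueError("base_hp must lie in [300, 2000] ms")
        if not RSA_BAND[0] <= self.rsa_freq <= RSA_BAND[1]:
            raise ValueError(f"rsa_freq must lie in {RSA_BAND} Hz")
        if not LF_BAND[0] <= self.lf_freq <= LF_BAND[1]:
            raise ValueError(f"lf_freq must lie in {LF_BAND} Hz")
        for name in (
            "beat_noise_sd",
            "transit_jitter_sd",
            "frame_ts_jitter_sd",
            "pixel_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline is asked to recover."""

    beat_times: np.ndarray  # s, cardiac (ECG-like) events, strictly increasing
    true_ibis: np.ndarray  # ms, true_ibis[k] = (beat_times[k+1]-beat_times[k])*1e3
    true_rsa_lnvar: float  # ln(ms^2), analytic A^2/2 of the RSA sinusoid
    true_lf_lnvar: float  # ln(ms^2)
    pulse_beat_times: np.ndarray  # s, delayed + jittered peripheral copies
    config: SynthConfig | None = None

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.true_ibis = np.asarray(self.true_ibis, dtype=float)
        self.pulse_beat_times = np.asarray(self.pulse_beat_times, dtype=float)
        if len(self.true_ibis) != len(self.beat_times) - 1:
            raise ValueError("need exactly one IBI per consecutive beat pair")
        if not np.all(np.diff(self.beat_times) > 0):
            raise ValueError("beat_times must be strictly increasing")


def _lnvar_of_sine(amp: float) -> float:
    """ln of the variance of an ``amp``-amplitude sinusoid (A^2/2), in ln(ms^2)."""
    return math.log(amp * amp / 2.0) if amp > 0 else -math.inf


def generate_ibi_series(config: SynthConfig) -> GroundTruth:
    """Lay down beats iteratively: the next beat follows after IBI(t)/1000 s.

    The modulators are evaluated at the current beat time (event-driven
    sampling), matching the beat-wise definition of the IBI. Raises if the
    modulation drives an IBI outside physiological bounds.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    beats = [0.0]
    t = 0.0
    while True:
        ibi = (
            config.base_hp
            + config.hp_slope * t
            + config.rsa_amp * math.sin(2 * math.pi * config.rsa_freq * t)
            + config.lf_amp * math.sin(2 * math.pi * config.lf_freq * t + config.lf_phase)
        )
        if config.beat_noise_sd > 0:
            ibi += rng.normal(0.0, config.beat_noise_sd)
        if not IBI_BOUNDS_MS[0] <= ibi <= IBI_BOUNDS_MS[1]:
            raise ValueError(
                f"degenerate physiology: IBI {ibi:.1f} ms at t={t:.2f} s is "
                f"outside {IBI_BOUNDS_MS} ms"
            )
        t_next = t + ibi / 1000.0
        if t_next > config.duration:
            break
        beats.append(t_next)
        t = t_next

    beat_times = np.array(beats)
    true_ibis = np.diff(beat_times) * 1000.0

    jitter = np.zeros(len(beat_times))
    if config.transit_jitter_sd > 0:
        jitter = rng.normal(0.0, config.transit_jitter_sd, size=len(beat_times))
    pulse_beat_times = beat_times + (config.transit_delay + jitter) / 1000.0
    # transit jitter must not reorder pulse arrivals
    if len(pulse_beat_times) > 1 and not np.all(np.diff(pulse_beat_times) > 0):
        pulse_beat_times = np.maximum.accumulate(pulse_beat_times + 1e-9 * np.arange(len(pulse_beat_times)))

    return GroundTruth(
        beat_times=beat_times,
        true_ibis=true_ibis,
        true_rsa_lnvar=_lnvar_of_sine(config.rsa_amp),
        true_lf_lnvar=_lnvar_of_sine(config.lf_amp),
        pulse_beat_times=pulse_beat_times,
        config=config,
    )


# --- waveform rendering -----------------------------------------------------

# ECG R-wave: narrow Gaussian, sigma chosen so the full width is ~15 ms.
ECG_SIGMA_S = 0.006
# Pulse wave: asymmetric bump, ~100 ms rise and a slower decay, one maximum.
# Support is truncated at 3 sigma so tachycardic trains (IBI ~600 ms) do not
# trip the overlap check; the residual step there is ~1% of the amplitude.
PULSE_RISE_SIGMA_S = 0.050
PULSE_DECAY_SIGMA_S = 0.120
_ECG_SUPPORT_SIGMAS = 4.0
_PULSE_SUPPORT_SIGMAS = 3.0


def _template_support(kind: str) -> tuple[float, float]:
    """(seconds before, seconds after) the template center with nonzero mass."""
    if kind == "ecg":
        w = _ECG_SUPPORT_SIGMAS * ECG_SIGMA_S
        return w, w
    return (
        _PULSE_SUPPORT_SIGMAS * PULSE_RISE_SIGMA_S,
        _PULSE_SUPPORT_SIGMAS * PULSE_DECAY_SIGMA_S,
    )


def _template(kind: str, dt: np.ndarray) -> np.ndarray:
    """Unit-amplitude template evaluated at offsets ``dt`` (s) from its peak."""
    if kind == "ecg":
        return np.exp(-0.5 * (dt / ECG_SIGMA_S) ** 2)
    # piecewise-Gaussian: fast rise, slow decay, single maximum at dt = 0
    out = np.empty_like(dt)
    rise = dt < 0
    out[rise] = np.exp(-0.5 * (dt[rise] / PULSE_RISE_SIGMA_S) ** 2)
    out[~rise] = np.exp(-0.5 * (dt[~rise] / PULSE_DECAY_SIGMA_S) ** 2)
    return out


def _sum_templates(centers: np.ndarray, times: np.ndarray, kind: str) -> np.ndarray:
    """Superpose one unit template per beat onto a zero baseline."""
    out = np.zeros_like(times)
    before, after = _template_support(kind)
    for c in centers:
        # works for uniform and jittered grids alike
        lo = int(np.searchsorted(times, c - before))
        hi = int(np.searchsorted(times, c + after))
        if hi > lo:
            out[lo:hi] += _template(kind, times[lo:hi] - c)
    return out


def render_waveform(truth: GroundTruth, kind: str = "ecg", fs: float = 1000.0) -> UniformSeries:
    """Render the beat train as an ECG-like or pulse-like uniform series.

    ``kind='ecg'`` centers narrow R-wave templates at the cardiac beat times;
    ``kind='pulse'`` centers broad asymmetric pulse templates at the delayed /
    jittered peripheral arrival times.
    """
    if kind not in ("ecg", "pulse"):
        raise ValueError("kind must be 'ecg' or 'pulse'")
    if fs < 250.0:
        raise ValueError("fs must be >= 250 Hz to resolve the templates")
    centers = truth.beat_times if kind == "ecg" else truth.pulse_beat_times
    before, after = _template_support(kind)
    if len(centers) > 1:
        min_gap = float(np.min(np.diff(centers)))
        if min_gap < before + after:
            raise ValueError(
                f"overlapping {kind} templates: minimum beat gap {min_gap * 1e3:.0f} ms "
                f"< template support {(before + after) * 1e3:.0f} ms"
            )
    t_end = centers[-1] + after
    n = int(round(t_end * fs)) + 1
    times = np.arange(n) / fs
    values = _sum_templates(centers, times, kind)
    return UniformSeries(values=values, fs=fs, t0=0.0, channel_tag=kind)


def add_noise(series: UniformSeries, snr_db: float, seed: int = 0) -> UniformSeries:
    """Add white Gaussian noise at a given SNR (signal RMS over noise RMS)."""
    rms = float(np.sqrt(np.mean(series.values**2)))
    sd = rms / 10 ** (snr_db / 20.0)
    rng = np.random.default_rng(seed)
    return series.with_values(series.values + rng.normal(0.0, sd, size=len(series)))


# --- video rendering --------------------------------------------------------

FRAME_SHAPE = (120, 160)  # rows, cols
ROI_SLICE = (slice(30, 90), slice(50, 110))  # centered 60 x 60 face block
_BACKGROUND = 60.0
_FACE_BASE = {"red": 150.0, "green": 140.0, "blue": 90.0}
_GAIN_REF = 128.0  # mid-gray reference for the illumination gain


def _base_frame() -> np.ndarray:
    """Static scene: flat background plus a face block with a smooth shading
    gradient (sub-LSB spatial variation, so ROI means resolve below 1 intensity
    step after 8-bit quantization)."""
    h, w = FRAME_SHAPE
    frame = np.full((h, w, 3), _BACKGROUND, dtype=float)
    rs, cs = ROI_SLICE
    n_r = rs.stop - rs.start
    n_c = cs.stop - cs.start
    shade = 0.1 * np.arange(n_r)[:, None] + 0.013 * np.arange(n_c)[None, :]
    shade -= shade.mean()
    for k, ch in enumerate(("red", "green", "blue")):
        frame[rs, cs, k] = _FACE_BASE[ch] + shade
    return frame


def pulse_activity(times: np.ndarray, pulse_beat_times: np.ndarray) -> np.ndarray:
    """Instantaneous blood-volume waveform in [0, 1] at the given times."""
    return _sum_templates(np.asarray(pulse_beat_times), np.asarray(times, float), "pulse")


def render_video(truth: GroundTruth, config: SynthConfig | None = None) -> tuple[FrameSequence, RoiMask]:
    """Render ~60 fps frames whose ROI green (and, more weakly, red) means dip
    when instantaneous blood volume is high — more blood absorbs more light, so
    the camera sees less reflected green/red.

    Illumination drift is a slow multiplicative gain applied to every pixel
    (common mode, cancelled by the green/red ratio); pixel noise is additive
    and independent. Per-frame timestamps are jittered around the nominal
    frame grid. Frames are quantized to the camera's 8-bit range.
    """
    config = config or truth.config
    if config is None:
        raise ValueError("a SynthConfig is required to render video")
    config.validate()
    rng = np.random.default_rng(config.seed + 1)  # independent of beat noise

    depth = {"green": config.modulation_depth_green, "red": config.modulation_depth_red}
    gain_amp = config.illum_drift_amp / _GAIN_REF
    lo = min(_FACE_BASE["green"] - depth["green"], _FACE_BASE["red"] - depth["red"])
    hi = max(_FACE_BASE.values()) + 1.0  # +1 for the shading gradient
    if lo * (1 - gain_amp) < 0 or hi * (1 + gain_amp) > 255:
        raise ValueError("modulation/drift exceed the 8-bit dynamic range [0, 255]")

    n_frames = int(np.floor(config.duration * config.frame_rate)) + 1
    ts = np.arange(n_frames) / config.frame_rate
    if config.frame_ts_jitter_sd > 0:
        ts = ts + rng.normal(0.0, config.frame_ts_jitter_sd / 1000.0, size=n_frames)
        ts[0] = max(ts[0], 0.0)
        ts = np.maximum.accumulate(ts + 1e-9 * np.arange(n_frames))

    p = pulse_activity(ts, truth.pulse_beat_times)
    gain = 1.0 + gain_amp * np.sin(2 * np.pi * config.illum_drift_freq * ts)

    base = _base_frame()
    rs, cs = ROI_SLICE
    frames = np.empty((n_frames, *FRAME_SHAPE, 3), dtype=np.uint8)
    for k in range(n_frames):
        frame = base.copy()
        frame[rs, cs, 0] -= depth["red"] * p[k]
        frame[rs, cs, 1] -= depth["green"] * p[k]
        frame *= gain[k]
        if config.pixel_noise_sd > 0:
            frame += rng.normal(0.0, config.pixel_noise_sd, size=frame.shape)
        np.clip(frame, 0, 255, out=frame)
        frames[k] = np.rint(frame).astype(np.uint8)

    mask = np.zeros(FRAME_SHAPE, dtype=bool)
    mask[rs, cs] = True
    seq = FrameSequence(frames=frames, timestamps=ts, nominal_rate=config.frame_rate)
    return seq, RoiMask(mask=mask)


# --- fixture writing --------------------------------------------------------

def write_fixture(truth: GroundTruth, outdir: str | Path, video: bool = False) -> Path:
    """Write a ground-truthed fixture tree: channels as delimited text, ground
    truth as JSON, and (optionally) frames as numbered PNGs + timestamps.csv."""
    from . import io as pcio  # local import: io pulls in pandas/imageio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ecg = render_waveform(truth, kind="ecg")
    pulse = render_waveform(truth, kind="pulse")
    pcio.write_uniform_series(outdir / "ecg.csv", ecg, tag="ecg")
    pcio.write_uniform_series(outdir / "pulse.csv", pulse, tag="elppg")
    gt = {
        "beat_times": truth.beat_times.tolist(),
        "true_ibis": truth.true_ibis.tolist(),
        "true_rsa_lnvar": truth.true_rsa_lnvar,
        "true_lf_lnvar": truth.true_lf_lnvar,
        "pulse_beat_times": truth.pulse_beat_times.tolist(),
        "config": asdict(truth.config) if truth.config else None,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(gt, indent=1))
    if video:
        seq, roi = render_video(truth)
        pcio.write_frames(outdir / "frames", seq, roi)
    return outdir
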