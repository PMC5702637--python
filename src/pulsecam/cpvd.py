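"""Cardio peak-valley detector (CPVD).

An adaptive windowed scanner: a window wide enough to contain at least one
physiological peak slides across the record in steps; within each window,
candidate local maxima above a distribution-derived threshold are refined by a
least-squares quadratic fit, which interpolates between samples so peak timing
resolves below the sampling grid. After the first three peaks, the window
width and step size adapt to the last inter-peak interval, so the scanner
tracks heart-rate accelerations and decelerations on its own.

Works for ECG R-waves (narrow, ~15 ms) and pulse-wave peaks (broad, ~10x
wider); valley detection is peak detection on the negated signal.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .series import UniformSeries

__all__ = [
    "DetectorParams",
    "PeakTrain",
    "IbiSeries",
    "detect_peaks",
    "detect_valleys",
    "refine_peak",
    "peaks_to_ibi",
]

logger = logging.getLogger(__name__)

IBI_BOUNDS_MS = (200.0, 3000.0)  # physiological interval bounds
MERGE_GAP_S = 0.2  # refined times closer than this are the same beat
WINDOW_CLAMP_MS = (300.0, 2000.0)


@dataclass
class DetectorParams:
    """Scanner geometry and thresholds.

    ECG defaults: 700 ms window / 400 ms step (guaranteeing one R-wave per
    window at ordinary heart rates) and a 15 ms quadratic-fit width matched to
    the R-wave. Pulse defaults are broader in proportion to the pulse wave.
    After adaptation kicks in, window = window_factor * last interval and
    step = step_factor * last interval; the factors reproduce the initial ECG
    ratios at a nominal 800 ms heart period (700/800 and 400/800).
    """

    mode: str = "ecg"  # 'ecg' | 'pulse'
    init_window: float = 700.0  # ms
    init_step: float = 400.0  # ms
    fit_width: float = 15.0  # ms, quadratic-fit span
    window_factor: float = 0.875
    step_factor: float = 0.5
    min_amp_range: float = 1e-6  # signal units; flatter windows are skipped
    # threshold within a window: median + threshold_frac * (max - median)
    threshold_frac: float = 0.5
    # record-wide amplitude floor: median + floor_frac * (max - median)
    floor_frac: float = 0.25
    # accepted peaks must reach amp_gate_frac * median of recent amplitudes
    amp_gate_frac: float = 0.4

    @classmethod
    def for_mode(cls, mode: str) -> "DetectorParams":
        if mode == "ecg":
            return cls()
        if mode == "pulse":
            return cls(mode="pulse", init_window=1200.0, init_step=600.0, fit_width=150.0)
        raise ValueError("mode must be 'ecg' or 'pulse'")

    def validate(self, fs: float) -> None:
        if not 0 < self.init_step <= self.init_window:
            raise ValueError("need 0 < init_step <= init_window")
        if self.fit_width * fs / 1000.0 < 3:
            raise ValueError("fit_width must span at least 3 samples at this fs")


@dataclass
class PeakTrain:
    """Detected events: (time, amplitude) pairs with strictly increasing times."""

    times: np.ndarray  # s
    amplitudes: np.ndarray  # signal units

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if len(self.times) != len(self.amplitudes):
            raise ValueError("times and amplitudes must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class IbiSeries:
    """Beats and the intervals between them.

    ``beat_times`` holds every beat event (n + 1 entries for n intervals);
    ``ibis[k]`` is the interval from beat k to beat k+1 in milliseconds.
    Intervals outside physiological bounds are flagged as artifacts, never
    silently dropped.
    """

    beat_times: np.ndarray  # s
    ibis: np.ndarray  # ms
    artifact: np.ndarray = field(default=None)  # bool per interval

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.ibis = np.asarray(self.ibis, dtype=float)
        if len(self.ibis) != len(self.beat_times) - 1:
            raise ValueError("need exactly one interval per consecutive beat pair")
        if not np.allclose(np.diff(self.beat_times) * 1000.0, self.ibis, atol=1e-6):
            raise ValueError("ibis must equal consecutive beat-time differences (ms)")
        if self.artifact is None:
            self.artifact = ~(
                (self.ibis >= IBI_BOUNDS_MS[0]) & (self.ibis <= IBI_BOUNDS_MS[1])
            )
        self.artifact = np.asarray(self.artifact, dtype=bool)

    def __len__(self) -> int:
        return len(self.ibis)


def refine_peak(
    values: np.ndarray, fs: float, index: int, fit_width_ms: float, t0: float = 0.0
) -> tuple[float, float] | None:
    """Sub-sample peak localization: least-squares parabola over the fit window.

    Returns the vertex ``(time, amplitude)``, or ``None`` when the fit is not
    concave (quadratic coefficient >= 0 means no local maximum) or when the
    window cannot be formed. The vertex is clamped to the fit window, so the
    refinement never moves a peak by more than half the fit width.
    """
    half = max(1, int(round(fit_width_ms * fs / 1000.0 / 2.0)))
    # clip to the array bounds so peaks at the record edges remain refinable
    lo, hi = max(0, index - half), min(len(values), index + half + 1)
    if hi - lo < 3:
        return None
    t_local = (np.arange(lo, hi) - index) / fs
    a, b, c = np.polyfit(t_local, values[lo:hi], 2)
    if a >= 0:
        return None  # convex: concavity test fails
    vertex = float(np.clip(-b / (2 * a), t_local[0], t_local[-1]))
    amplitude = float(a * vertex**2 + b * vertex + c)
    return t0 + index / fs + vertex, amplitude


def _local_maxima(window: np.ndarray, left_edge: bool = False, right_edge: bool = False) -> np.ndarray:
    """Indices of strict-left / non-strict-right local maxima inside a window.

    When the window abuts the start or end of the record, the boundary sample
    itself may be a (half-seen) peak and is admitted as a candidate."""
    if len(window) < 3:
        return np.array([], dtype=int)
    interior = (window[1:-1] > window[:-2]) & (window[1:-1] >= window[2:])
    idx = list(np.flatnonzero(interior) + 1)
    if left_edge and window[0] > window[1]:
        idx.insert(0, 0)
    if right_edge and window[-1] > window[-2]:
        idx.append(len(window) - 1)
    return np.array(idx, dtype=int)


def detect_peaks(s: UniformSeries, params: DetectorParams | None = None) -> PeakTrain:
    """Run the adaptive scanner over a uniform series and return the peak train.

    Within each window: threshold = median + threshold_frac * (max - median) of
    the window samples (robust to baseline, and the window maximum always
    qualifies); candidates are quadratic-refined; when several survive, the
    earliest is compared with the window maximum and the larger amplitude wins.
    Duplicate detections from overlapping windows are merged (times closer
    than 200 ms are one beat; the higher amplitude is kept).
    """
    params = params or DetectorParams()
    params.validate(s.fs)
    fs = s.fs
    # scan only the transient-free region flagged by the conditioning stage
    skip = int(round(s.edge_exclude_s * fs))
    v = s.values[skip : len(s.values) - skip] if skip else s.values
    t_start = s.t0 + skip / fs
    n = len(v)
    if (n - 1) / fs < 2 * params.init_window / 1000.0:
        raise ValueError("series shorter than two initial windows")
    if float(np.ptp(v)) < params.min_amp_range:
        warnings.warn("signal range below min_amp_range; no peaks detected")
        return PeakTrain(times=np.array([]), amplitudes=np.array([]))

    global_floor = float(np.median(v) + params.floor_frac * (np.max(v) - np.median(v)))

    w = max(3, int(round(params.init_window * fs / 1000.0)))
    step = max(1, int(round(params.init_step * fs / 1000.0)))
    times: list[float] = []
    amps: list[float] = []

    pos = 0
    while pos < n - 2:
        hi = min(pos + w, n)
        window = v[pos:hi]
        if len(window) < 3:
            break
        if float(np.ptp(window)) >= params.min_amp_range:
            med = float(np.median(window))
            thr = max(med + params.threshold_frac * (float(window.max()) - med), global_floor)
            refined: list[tuple[float, float]] = []
            for i in _local_maxima(window, left_edge=(pos == 0), right_edge=(hi == n)):
                if window[i] < thr:
                    continue
                r = refine_peak(v, fs, pos + i, params.fit_width, t0=t_start)
                if r is not None:
                    refined.append(r)
            if refined and len(amps) >= 3:
                gate = params.amp_gate_frac * float(np.median(amps[-5:]))
                refined = [r for r in refined if r[1] >= gate]
            if refined:
                first = refined[0]
                wmax = max(refined, key=lambda r: r[1])
                chosen = wmax if wmax[1] > first[1] else first
                _accept(times, amps, chosen)
                if len(times) >= 3:
                    delta_ms = (times[-1] - times[-2]) * 1000.0
                    win_ms = float(np.clip(params.window_factor * delta_ms, *WINDOW_CLAMP_MS))
                    w = max(3, int(round(win_ms * fs / 1000.0)))
                    step = max(1, int(round(params.step_factor * delta_ms * fs / 1000.0)))
        pos += step

    t = np.array(times)
    a = np.array(amps)
    logger.info(
        "CPVD %s: %d peaks (threshold_frac=%.2f floor_frac=%.2f amp_gate=%.2f "
        "window_factor=%.3f step_factor=%.2f)",
        params.mode, len(t), params.threshold_frac, params.floor_frac,
        params.amp_gate_frac, params.window_factor, params.step_factor,
    )
    return PeakTrain(times=t, amplitudes=a)


def _accept(times: list, amps: list, peak: tuple[float, float]) -> None:
    """Append a refined peak, merging with the previous one when they are the
    same beat seen through overlapping windows."""
    t, a = peak
    if times and t - times[-1] < MERGE_GAP_S:
        if a > amps[-1]:
            times[-1], amps[-1] = t, a
        return
    if times and t <= times[-1]:
        return
    times.append(t)
    amps.append(a)


def detect_valleys(s: UniformSeries, params: DetectorParams | None = None) -> PeakTrain:
    """Valley detection = peak detection on the negated signal (one code path).

    Returned amplitudes are the valley depths on the original signal."""
    negated = s.with_values(-s.values)
    train = detect_peaks(negated, params)
    return PeakTrain(times=train.times, amplitudes=-train.amplitudes)


def peaks_to_ibi(train: PeakTrain) -> IbiSeries:
    """Consecutive peak-time differences, in milliseconds."""
    if len(train) < 2:
        raise ValueError("need at least 2 peaks to form intervals")
    ibis = np.diff(train.times) * 1000.0
    return IbiSeries(beat_times=train.times.copy(), ibis=ibis)
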