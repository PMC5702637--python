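"""Heart-rate-variability quantification from an interbeat-interval series.

The chain follows the Porges-Bohrer construction: the beat-event series is
resampled to an equally spaced 2 Hz heart-period series; a moving polynomial
filter (a sliding local least-squares cubic — i.e. a Savitzky-Golay trend)
removes slow trend and oscillations below the band of interest; the residual
is band-passed with a Kaiser-window FIR filter (0.12-0.40 Hz for respiratory
sinus arrhythmia, 0.04-0.10 Hz for the low-frequency component); and the
filtered series is cut into sequential 30-s epochs whose ln-transformed
variances [ln(ms^2)] are averaged into the segment estimate. Heart period (HP)
is simply the mean of the 2 Hz series over the segment.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .cpvd import IbiSeries
from .series import UniformSeries

__all__ = [
    "SegmentLog",
    "Hp2HzSeries",
    "HrvEstimate",
    "segment_by_tasks",
    "segment_ibi",
    "resample_2hz",
    "heart_period",
    "moving_polynomial_filter",
    "kaiser_bandpass",
    "epoch_ln_variance",
    "rsa_estimate",
    "lf_estimate",
    "window_average",
    "hrv_summary",
    "RSA_BAND",
    "LF_BAND",
]

FS_2HZ = 2.0
RSA_BAND = (0.12, 0.40)  # Hz
LF_BAND = (0.04, 0.10)  # Hz
RSA_MPF_POINTS = 21
LF_MPF_POINTS = 51
EPOCH_S = 30.0
HP_BOUNDS_MS = (200.0, 3000.0)
# Kaiser design: transition width and stopband attenuation
KAISER_TRANSITION_HZ = 0.04
KAISER_ATTEN_DB = 60.0
MAX_MISSING_FRAC = 0.10


@dataclass
class SegmentLog:
    """Task time log: (label, start_s, end_s) per experimental condition."""

    entries: list  # of (label, start, end)

    def __post_init__(self) -> None:
        cleaned = []
        for label, start, end in self.entries:
            start, end = float(start), float(end)
            if not start < end:
                raise ValueError(f"segment '{label}': start must precede end")
            cleaned.append((str(label), start, end))
        cleaned.sort(key=lambda e: e[1])
        for (l1, _, e1), (l2, s2, _) in zip(cleaned, cleaned[1:]):
            if s2 < e1:
                raise ValueError(f"segments '{l1}' and '{l2}' overlap")
        self.entries = cleaned

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class Hp2HzSeries:
    """Equally spaced heart-period series at 2 Hz; NaN marks missing bins."""

    values: np.ndarray  # ms
    t0: float = 0.0  # s

    fs: float = FS_2HZ

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if len(finite) and (
            finite.min() < HP_BOUNDS_MS[0] or finite.max() > HP_BOUNDS_MS[1]
        ):
            raise ValueError(f"heart-period values must lie in {HP_BOUNDS_MS} ms")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.fs

    @property
    def missing_frac(self) -> float:
        return float(np.mean(~np.isfinite(self.values))) if len(self.values) else 1.0


@dataclass
class HrvEstimate:
    """Per-segment summary: HP in ms, RSA and LF in ln(ms^2).

    RSA/LF are the means of their 30-s epoch values; NaN marks a segment where
    the estimate was unavailable (too short or too many missing bins)."""

    segment_label: str
    hp: float
    rsa: float
    lf: float
    rsa_epoch_values: np.ndarray = field(default_factory=lambda: np.array([]))
    lf_epoch_values: np.ndarray = field(default_factory=lambda: np.array([]))
    note: str = ""


def segment_by_tasks(series: UniformSeries, log: SegmentLog) -> dict:
    """Slice a uniform series at the task boundaries; labels are preserved."""
    out = {}
    t_start, t_end = series.t0, series.t0 + series.duration
    for label, start, end in log:
        if start < t_start - 1e-9 or end > t_end + 1e-9:
            raise ValueError(
                f"segment '{label}' [{start}, {end}] outside series span "
                f"[{t_start:.3f}, {t_end:.3f}]"
            )
        i0 = int(np.ceil((start - series.t0) * series.fs - 1e-9))
        i1 = int(np.floor((end - series.t0) * series.fs + 1e-9)) + 1
        out[label] = UniformSeries(
            values=series.values[i0:i1],
            fs=series.fs,
            t0=series.t0 + i0 / series.fs,
            channel_tag=series.channel_tag,
            edge_exclude_s=0.0,
        )
    return out


def segment_ibi(ibi: IbiSeries, log: SegmentLog) -> dict:
    """Per-task sub-series of an IBI series (intervals fully inside a segment)."""
    out = {}
    span = (ibi.beat_times[0], ibi.beat_times[-1])
    for label, start, end in log:
        if start < span[0] - 1e-9 or end > span[1] + 1e-9:
            raise ValueError(f"segment '{label}' outside the beat span {span}")
        keep = (ibi.beat_times >= start) & (ibi.beat_times <= end)
        idx = np.flatnonzero(keep)
        if len(idx) < 2:
            raise ValueError(f"segment '{label}' contains fewer than 2 beats")
        sl = slice(idx[0], idx[-1] + 1)
        out[label] = IbiSeries(
            beat_times=ibi.beat_times[sl],
            ibis=ibi.ibis[sl.start : sl.stop - 1],
            artifact=ibi.artifact[sl.start : sl.stop - 1],
        )
    return out


def _time_weighted_bins(ibi: IbiSeries, width_s: float, t_start: float, n_bins: int) -> np.ndarray:
    """Time-weighted mean IBI per bin; NaN where a bin has no (clean) coverage.

    Each interval [beat_k, beat_k+1) contributes its IBI value weighted by its
    overlap with the bin; artifact-flagged intervals contribute nothing, so
    bins they touch are only covered by their clean neighbors (or go missing).
    """
    edges = t_start + width_s * np.arange(n_bins + 1)
    acc = np.zeros(n_bins)
    cov = np.zeros(n_bins)
    starts = ibi.beat_times[:-1]
    ends = ibi.beat_times[1:]
    for k in range(len(ibi.ibis)):
        if ibi.artifact[k]:
            continue
        b0 = int(np.floor((starts[k] - t_start) / width_s))
        b1 = int(np.floor((ends[k] - t_start) / width_s - 1e-12))
        for b in range(max(b0, 0), min(b1, n_bins - 1) + 1):
            overlap = min(ends[k], edges[b + 1]) - max(starts[k], edges[b])
            if overlap > 0:
                acc[b] += overlap * ibi.ibis[k]
                cov[b] += overlap
        # artifact gap handling: uncovered stretches simply leave cov at 0
    with np.errstate(invalid="ignore"):
        values = np.where(cov > 1e-12, acc / np.maximum(cov, 1e-300), np.nan)
    return values


def resample_2hz(ibi: IbiSeries) -> Hp2HzSeries:
    """Resample the beat-event series to equally spaced 500 ms bins.

    Each bin receives the time-weighted average of the IBI values of the beats
    overlapping it (the weights are the fractions of the bin each interval
    covers). Bins overlapping only artifact-flagged intervals are missing."""
    if len(ibi) < 1:
        raise ValueError("need at least 1 interval to resample")
    width = 1.0 / FS_2HZ
    t_start = float(ibi.beat_times[0])
    span = float(ibi.beat_times[-1] - ibi.beat_times[0])
    n_bins = max(int(np.floor(span / width + 1e-9)), 1)
    values = _time_weighted_bins(ibi, width, t_start, n_bins)
    return Hp2HzSeries(values=values, t0=t_start)


def heart_period(h: Hp2HzSeries) -> float:
    """Mean of the 2 Hz heart-period series (ms), ignoring missing bins."""
    finite = h.values[np.isfinite(h.values)]
    if len(finite) == 0:
        raise ValueError("all bins missing; heart period undefined")
    return float(np.mean(finite))


def moving_polynomial_filter(
    h: Hp2HzSeries | UniformSeries, order: int = 3, points: int = RSA_MPF_POINTS
) -> tuple[UniformSeries, UniformSeries]:
    """Sliding local least-squares polynomial trend and its residual.

    ``trend[k]`` is the value at the center of a degree-``order`` fit over the
    ``points`` samples centered at k; the residual is input minus trend. The
    (points-1)/2 edge samples on each side, where the centered fit cannot be
    formed, are trimmed rather than extrapolated. Reproduces any global
    polynomial of degree <= order exactly (zero residual) on interior points.
    """
    values = np.asarray(h.values, dtype=float)
    fs = getattr(h, "fs", FS_2HZ)
    if points % 2 != 1 or points < order + 2:
        raise ValueError("points must be odd and exceed the polynomial order")
    if len(values) < points:
        raise ValueError(f"series length {len(values)} shorter than the {points}-point window")
    if np.any(~np.isfinite(values)):
        raise ValueError("missing values must be interpolated before filtering")
    trend = signal.savgol_filter(values, points, order, mode="interp")
    half = (points - 1) // 2
    sl = slice(half, len(values) - half)
    t0 = float(h.t0) + half / fs
    trend_s = UniformSeries(values=trend[sl], fs=fs, t0=t0, channel_tag="trend")
    resid_s = UniformSeries(values=values[sl] - trend[sl], fs=fs, t0=t0, channel_tag="residual")
    return trend_s, resid_s


def design_kaiser(band: tuple[float, float], fs: float = FS_2HZ) -> np.ndarray:
    """Kaiser-window FIR band-pass taps: 60 dB stopband, 0.04 Hz transitions,
    odd length (exact integer group delay for compensation)."""
    numtaps, beta = signal.kaiserord(KAISER_ATTEN_DB, KAISER_TRANSITION_HZ / (fs / 2))
    if numtaps % 2 == 0:
        numtaps += 1
    return signal.firwin(
        numtaps, list(band), window=("kaiser", beta), pass_zero=False, fs=fs
    )


def kaiser_bandpass(residual: UniformSeries, band: tuple[float, float] = RSA_BAND) -> UniformSeries:
    """Linear-phase FIR band-pass, delay-compensated (centered convolution)."""
    if not 0 < band[0] < band[1] < residual.fs / 2:
        raise ValueError(f"band {band} invalid at fs={residual.fs}")
    taps = design_kaiser(band, residual.fs)
    if len(residual) < len(taps):
        raise ValueError(
            f"series of {len(residual)} samples shorter than the {len(taps)}-tap filter"
        )
    filtered = np.convolve(residual.values, taps, mode="same")
    return residual.with_values(filtered, channel_tag="bandpassed")


def epoch_ln_variance(filtered: UniformSeries, epoch_s: float = EPOCH_S) -> tuple[np.ndarray, float]:
    """Cut into sequential non-overlapping epochs; ln of the sample variance of
    each; mean across epochs. A trailing partial epoch is discarded."""
    n_per = int(round(epoch_s * filtered.fs))
    n_epochs = len(filtered) // n_per
    if n_epochs < 1:
        raise ValueError(f"need at least one complete {epoch_s:.0f}-s epoch")
    chunks = filtered.values[: n_epochs * n_per].reshape(n_epochs, n_per)
    variances = chunks.var(axis=1, ddof=1)
    if np.any(variances <= 0):
        raise ValueError(
            "zero variance within an epoch (ln undefined); the signal is "
            "constant there — check filtering and segment selection"
        )
    epoch_values = np.log(variances)
    return epoch_values, float(np.mean(epoch_values))


def _interpolate_missing(h: Hp2HzSeries) -> Hp2HzSeries | None:
    """Linear interpolation across missing bins; None when > 10% are missing."""
    if h.missing_frac > MAX_MISSING_FRAC:
        return None
    values = h.values.copy()
    bad = ~np.isfinite(values)
    if bad.any():
        idx = np.arange(len(values))
        values[bad] = np.interp(idx[bad], idx[~bad], values[~bad])
    return Hp2HzSeries(values=values, t0=h.t0)


def _band_estimate(h: Hp2HzSeries, points: int, band: tuple[float, float]):
    clean = _interpolate_missing(h)
    if clean is None:
        return np.array([]), float("nan"), "unavailable: > 10% of 2 Hz bins missing"
    _, residual = moving_polynomial_filter(clean, order=3, points=points)
    try:
        filtered = kaiser_bandpass(residual, band)
        epoch_values, mean = epoch_ln_variance(filtered)
    except ValueError as exc:
        return np.array([]), float("nan"), f"unavailable: {exc}"
    return epoch_values, mean, ""


def rsa_estimate(h: Hp2HzSeries) -> tuple[np.ndarray, float]:
    """Respiratory sinus arrhythmia, ln(ms^2): 21-point cubic MPF detrend ->
    0.12-0.40 Hz Kaiser FIR -> mean ln-variance of 30-s epochs."""
    epoch_values, mean, note = _band_estimate(h, RSA_MPF_POINTS, RSA_BAND)
    if note:
        raise ValueError(note)
    return epoch_values, mean


def lf_estimate(h: Hp2HzSeries) -> tuple[np.ndarray, float]:
    """Low-frequency HRV, ln(ms^2): 51-point cubic MPF detrend ->
    0.04-0.10 Hz Kaiser FIR -> mean ln-variance of 30-s epochs."""
    epoch_values, mean, note = _band_estimate(h, LF_MPF_POINTS, LF_BAND)
    if note:
        raise ValueError(note)
    return epoch_values, mean


def window_average(ibi: IbiSeries, window_s: float) -> Hp2HzSeries:
    """Time-weighted mean IBI over sequential non-overlapping windows (2 or 5 s
    are the conventional choices for stabilizing camera-derived estimates).
    Windows with no beat coverage are marked missing. Returned as a series at
    1/window_s Hz starting at the first beat."""
    if len(ibi) == 0:
        raise ValueError("empty IBI series")
    t_start = float(ibi.beat_times[0])
    span = float(ibi.beat_times[-1] - t_start)
    n_bins = max(int(np.floor(span / window_s + 1e-9)), 1)
    values = _time_weighted_bins(ibi, window_s, t_start, n_bins)
    return Hp2HzSeries(values=values, t0=t_start, fs=1.0 / window_s)


def hrv_summary(ibi: IbiSeries, log: SegmentLog | None = None) -> list[HrvEstimate]:
    """Per-segment HP, RSA, and LF. Without a log the whole record is one
    segment labelled ``all``. Segments too short for a band estimate report
    NaN with an explanatory note instead of failing the run."""
    if log is None:
        log = SegmentLog([("all", float(ibi.beat_times[0]), float(ibi.beat_times[-1]))])
    estimates = []
    for label, sub in segment_ibi(ibi, log).items():
        h = resample_2hz(sub)
        hp = heart_period(h)
        rsa_vals, rsa, rsa_note = _band_estimate(h, RSA_MPF_POINTS, RSA_BAND)
        lf_vals, lf, lf_note = _band_estimate(h, LF_MPF_POINTS, LF_BAND)
        note = "; ".join(x for x in (rsa_note and f"RSA {rsa_note}", lf_note and f"LF {lf_note}") if x)
        estimates.append(
            HrvEstimate(
                segment_label=label, hp=hp, rsa=rsa, lf=lf,
                rsa_epoch_values=rsa_vals, lf_epoch_values=lf_vals, note=note,
            )
        )
    return estimates
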