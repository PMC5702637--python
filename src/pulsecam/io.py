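"""Readers and writers for the pipeline's on-disk formats.

All formats are plain text or PNG: channel series as delimited text
(``time_s,<tag>`` header), frame stacks as numbered PNGs plus a
``timestamps.csv``, the task log as ``label,start_s,end_s``, peak trains and
IBI series as CSV, and reports / ground truth as JSON. Times on disk are
seconds; IBIs are milliseconds — the headers keep the mixed units explicit.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cpvd import IbiSeries, PeakTrain
from .hrv import HrvEstimate, SegmentLog
from .series import FrameSequence, RoiMask, UniformSeries

__all__ = [
    "write_uniform_series",
    "read_uniform_series",
    "read_channels",
    "write_frames",
    "read_frames",
    "write_peaks",
    "read_peaks",
    "write_ibi",
    "read_ibi",
    "read_segment_log",
    "write_segment_log",
    "write_report",
    "read_ground_truth",
]

_FS_TOL = 0.01  # relative deviation of sample spacing that still counts as uniform


def write_uniform_series(path, s: UniformSeries, tag: str | None = None) -> None:
    tag = tag or s.channel_tag
    df = pd.DataFrame({"time_s": s.times, tag: s.values})
    df.to_csv(path, index=False, float_format="%.9g")


def _series_from_columns(time_s: np.ndarray, values: np.ndarray, tag: str) -> UniformSeries:
    dt = np.diff(time_s)
    if len(dt) == 0:
        raise ValueError("channel file must contain at least 2 samples")
    if np.any(dt <= 0):
        raise ValueError("time column must be strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > _FS_TOL * med:
        raise ValueError("inconsistent sampling interval; not a uniform series")
    return UniformSeries(values=values, fs=1.0 / med, t0=float(time_s[0]), channel_tag=tag)


def read_uniform_series(path) -> UniformSeries:
    df = pd.read_csv(path)
    if df.shape[1] < 2 or df.columns[0] != "time_s":
        raise ValueError(f"{path}: expected a 'time_s' column followed by a channel column")
    tag = df.columns[1]
    return _series_from_columns(df["time_s"].to_numpy(), df[tag].to_numpy(), tag)


def read_channels(paths) -> dict:
    """Read one or more channel files into tagged UniformSeries.

    A file may hold several channel columns after ``time_s``. A column named
    ``sync`` is treated as a synchronization pulse: each file's t0 is shifted
    so its sync onset (first crossing of half range) lands at time zero,
    aligning channels recorded by different devices.
    """
    channels: dict[str, UniformSeries] = {}
    for path in map(Path, np.atleast_1d(paths)):
        df = pd.read_csv(path)
        if df.columns[0] != "time_s":
            raise ValueError(f"{path}: first column must be time_s")
        time_s = df["time_s"].to_numpy(dtype=float)
        offset = 0.0
        if "sync" in df.columns:
            sync = df["sync"].to_numpy(dtype=float)
            half = (sync.min() + sync.max()) / 2.0
            onset = np.flatnonzero(sync > half)
            if len(onset) == 0:
                raise ValueError(f"{path}: sync column never rises")
            offset = -float(time_s[onset[0]])
        for tag in df.columns[1:]:
            if tag == "sync":
                continue
            if tag in channels:
                raise ValueError(f"duplicate channel tag '{tag}'")
            s = _series_from_columns(time_s, df[tag].to_numpy(dtype=float), tag)
            s.t0 += offset
            channels[tag] = s
    return channels


def write_frames(outdir, seq: FrameSequence, roi: RoiMask | None = None) -> Path:
    """Numbered PNG frames + timestamps.csv (+ roi_mask.png when given)."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for k, frame in enumerate(seq.frames):
        iio.imwrite(outdir / f"frame_{k:05d}.png", np.asarray(frame, dtype=np.uint8))
    pd.DataFrame(
        {"frame_index": np.arange(len(seq)), "time_s": seq.timestamps}
    ).to_csv(outdir / "timestamps.csv", index=False, float_format="%.9g")
    if roi is not None:
        iio.imwrite(outdir / "roi_mask.png", (roi.mask * np.uint8(255)))
    return outdir


def read_frames(indir) -> tuple[FrameSequence, RoiMask | None]:
    import imageio.v3 as iio

    indir = Path(indir)
    ts = pd.read_csv(indir / "timestamps.csv")
    files = sorted(indir.glob("frame_*.png"))
    if len(files) != len(ts):
        raise ValueError("frame count does not match timestamps.csv")
    frames = np.stack([iio.imread(f) for f in files])
    dt = np.diff(ts["time_s"].to_numpy())
    rate = 1.0 / float(np.median(dt)) if len(dt) else 1.0
    seq = FrameSequence(frames=frames, timestamps=ts["time_s"].to_numpy(), nominal_rate=rate)
    roi = None
    roi_path = indir / "roi_mask.png"
    if roi_path.exists():
        roi = RoiMask(mask=iio.imread(roi_path) > 127)
    return seq, roi


def write_peaks(path, train: PeakTrain) -> None:
    pd.DataFrame({"time_s": train.times, "amplitude": train.amplitudes}).to_csv(
        path, index=False, float_format="%.9g"
    )


def read_peaks(path) -> PeakTrain:
    df = pd.read_csv(path)
    return PeakTrain(times=df["time_s"].to_numpy(), amplitudes=df["amplitude"].to_numpy())


def write_ibi(path, ibi: IbiSeries) -> None:
    pd.DataFrame(
        {
            "time_s": ibi.beat_times[:-1],
            "ibi_ms": ibi.ibis,
            "artifact": ibi.artifact.astype(int),
        }
    ).to_csv(path, index=False, float_format="%.9g")


def read_ibi(path) -> IbiSeries:
    df = pd.read_csv(path)
    lead = df["time_s"].to_numpy(dtype=float)
    ibis = df["ibi_ms"].to_numpy(dtype=float)
    beat_times = np.append(lead, lead[-1] + ibis[-1] / 1000.0)
    artifact = df["artifact"].to_numpy(dtype=bool) if "artifact" in df else None
    return IbiSeries(beat_times=beat_times, ibis=ibis, artifact=artifact)


def read_segment_log(path) -> SegmentLog:
    df = pd.read_csv(path)
    return SegmentLog(list(df[["label", "start_s", "end_s"]].itertuples(index=False, name=None)))


def write_segment_log(path, log: SegmentLog) -> None:
    pd.DataFrame(log.entries, columns=["label", "start_s", "end_s"]).to_csv(path, index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if hasattr(obj, "__dataclass_fields__"):
            return {k: getattr(obj, k) for k in obj.__dataclass_fields__}
        return super().default(obj)


def write_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=1, cls=_NumpyEncoder, allow_nan=True))


def estimates_to_frame(estimates: list[HrvEstimate], channel: str) -> pd.DataFrame:
    """Flat one-row-per-segment table of HRV estimates for a channel."""
    return pd.DataFrame(
        {
            "channel": channel,
            "segment": [e.segment_label for e in estimates],
            "hp_ms": [e.hp for e in estimates],
            "rsa_lnms2": [e.rsa for e in estimates],
            "lf_lnms2": [e.lf for e in estimates],
            "note": [e.note for e in estimates],
        }
    )


def read_ground_truth(path) -> dict:
    return json.loads(Path(path).read_text())
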