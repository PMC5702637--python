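"""Core containers shared across the pipeline.

All times are seconds; interbeat intervals are milliseconds. Every uniformly
sampled series carries an absolute start time ``t0`` so channels recorded by
different devices can be aligned on a common clock.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["IrregularSeries", "UniformSeries", "FrameSequence", "RoiMask"]


@dataclass
class IrregularSeries:
    """A 1-D signal sampled at strictly increasing but non-uniform times.

    This is what a free-running camera produces: one value per frame, paired
    with the frame's timestamp.
    """

    times: np.ndarray  # s
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class UniformSeries:
    """A fixed-rate 1-D signal — the lingua franca of conditioning and HRV.

    ``edge_exclude_s`` marks a transient region at each end (set by filtering
    stages) that downstream peak detection must ignore.
    """

    values: np.ndarray
    fs: float  # Hz
    t0: float = 0.0  # s, absolute start time
    channel_tag: str = "synthetic"
    edge_exclude_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.fs

    @property
    def duration(self) -> float:
        """Span from first to last sample, in seconds."""
        return max(len(self.values) - 1, 0) / self.fs

    def with_values(self, values: np.ndarray, **changes) -> "UniformSeries":
        """Copy of this series with new sample values (same grid)."""
        return replace(self, values=np.asarray(values, dtype=float), **changes)


@dataclass
class FrameSequence:
    """A timestamped stack of H x W x 3 color frames (8-bit intensity range)."""

    frames: np.ndarray  # (n, H, W, 3)
    timestamps: np.ndarray  # s, strictly increasing
    nominal_rate: float  # Hz

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must have shape (n, H, W, 3)")
        if len(self.frames) != len(self.timestamps):
            raise ValueError("one timestamp per frame required")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not self.nominal_rate > 0:
            raise ValueError("nominal_rate must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple:
        return self.frames.shape[1:3]


@dataclass
class RoiMask:
    """Boolean pixel mask selecting the skin region of interest."""

    mask: np.ndarray  # (H, W) bool

    MIN_PIXELS = 100

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if int(self.mask.sum()) < self.MIN_PIXELS:
            raise ValueError(
                f"ROI must contain at least {self.MIN_PIXELS} pixels, "
                f"got {int(self.mask.sum())}"
            )

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())
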