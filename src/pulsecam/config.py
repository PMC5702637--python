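"""Run configuration for the full pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .cpvd import DetectorParams

__all__ = ["ChannelConfig", "RunConfig", "load_config"]


@dataclass
class ChannelConfig:
    tag: str  # unique channel name, e.g. 'ecg', 'elppg', 'phyc'
    path: str | None = None  # channel CSV, or None when derived from frames
    kind: str = "pulse"  # detector mode: 'ecg' | 'pulse'
    frames_dir: str | None = None  # video source (pulse extraction path)
    bandpass: bool = False  # apply 0.5-2 Hz conditioning before detection


@dataclass
class RunConfig:
    channels: list = field(default_factory=list)  # of ChannelConfig
    segment_log: str | None = None
    output_dir: str = "pulsecam_out"
    seed: int = 0
    log_level: str = "INFO"
    detector_overrides: dict = field(default_factory=dict)  # tag -> DetectorParams kwargs
    window_averages_s: tuple = (2.0, 5.0)
    match_tolerance_ms: float = 250.0
    make_plots: bool = False

    def detector_for(self, channel: ChannelConfig) -> DetectorParams:
        params = DetectorParams.for_mode(channel.kind)
        for key, value in self.detector_overrides.get(channel.tag, {}).items():
            setattr(params, key, value)
        return params

    def validate(self) -> None:
        tags = [c.tag for c in self.channels]
        if len(tags) != len(set(tags)):
            raise ValueError("channel tags must be unique")
        for c in self.channels:
            if c.path is None and c.frames_dir is None:
                raise ValueError(f"channel '{c.tag}': needs a path or a frames_dir")
            for p in (c.path, c.frames_dir):
                if p is not None and not Path(p).exists():
                    raise ValueError(f"channel '{c.tag}': {p} does not exist")
        if self.segment_log is not None and not Path(self.segment_log).exists():
            raise ValueError(f"segment log {self.segment_log} does not exist")


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML mapping; file values override defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    channels = [ChannelConfig(**c) for c in raw.pop("channels", [])]
    cfg = RunConfig(channels=channels, **raw)
    return cfg
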