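"""End-to-end orchestration: channels -> beats -> HRV -> sensor agreement.

Per channel: detect beats, form IBIs, estimate per-segment HP/RSA/LF.
Per channel pair: match beats, Bland-Altman, regression at beat level and on
2-s and 5-s window averages. Every intermediate product and every resolved
parameter is written to the output directory so a run can be audited.
"""
from __future__ import annotations

import logging
from dataclasses import asdict
from itertools import combinations
from pathlib import Path

import numpy as np

from . import agreement, conditioning, cpvd, hrv
from . import io as pcio
from .config import ChannelConfig, RunConfig
from .pulse_extract import video_to_pulse
from .series import UniformSeries

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def _load_channel(cfg: ChannelConfig) -> UniformSeries:
    if cfg.frames_dir is not None:
        frames, roi = pcio.read_frames(cfg.frames_dir)
        if roi is None:
            raise ValueError(f"channel '{cfg.tag}': frames_dir has no roi_mask.png")
        s = video_to_pulse(frames, roi)
    else:
        s = pcio.read_uniform_series(cfg.path)
        if cfg.bandpass:
            s = conditioning.bandpass(conditioning.center_on_zero(s))
            s = conditioning.first_derivative(s)
    s.channel_tag = cfg.tag
    return s


def _windowed_r2(a: cpvd.IbiSeries, b: cpvd.IbiSeries, window_s: float) -> float:
    wa = hrv.window_average(a, window_s)
    wb = hrv.window_average(b, window_s)
    # align on the common window grid (both start at their own first beat)
    n = min(len(wa), len(wb))
    va, vb = wa.values[:n], wb.values[:n]
    ok = np.isfinite(va) & np.isfinite(vb)
    fit = agreement.linear_fit(va[ok], vb[ok])
    return fit.r_squared


def run_pipeline(config: RunConfig) -> dict:
    """Run the full measurement chain and return (and write) the report bundle."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    log = pcio.read_segment_log(config.segment_log) if config.segment_log else None

    report: dict = {"channels": {}, "pairs": {}, "parameters": {"seed": config.seed}}
    ibis: dict[str, cpvd.IbiSeries] = {}
    hrv_tables = []
    for ch in config.channels:
        try:
            series = _load_channel(ch)
            params = config.detector_for(ch)
            report["parameters"][ch.tag] = asdict(params)
            train = cpvd.detect_peaks(series, params)
            ibi = cpvd.peaks_to_ibi(train)
        except (ValueError, OSError) as exc:
            raise RuntimeError(f"stage failed for channel '{ch.tag}': {exc}") from exc
        ibis[ch.tag] = ibi
        pcio.write_peaks(outdir / f"{ch.tag}_peaks.csv", train)
        pcio.write_ibi(outdir / f"{ch.tag}_ibi.csv", ibi)
        ch_log = log
        if ch_log is None:
            ch_log = hrv.SegmentLog(
                [("all", float(ibi.beat_times[0]), float(ibi.beat_times[-1]))]
            )
        estimates = hrv.hrv_summary(ibi, ch_log)
        hrv_tables.append(pcio.estimates_to_frame(estimates, ch.tag))
        report["channels"][ch.tag] = {
            "n_beats": len(train),
            "n_artifact_intervals": int(ibi.artifact.sum()),
            "segments": {
                e.segment_label: {
                    "hp_ms": e.hp,
                    "rsa_lnms2": e.rsa,
                    "lf_lnms2": e.lf,
                    "rsa_epochs": e.rsa_epoch_values,
                    "lf_epochs": e.lf_epoch_values,
                    "note": e.note,
                }
                for e in estimates
            },
        }

    for tag_a, tag_b in combinations(ibis, 2):
        try:
            pairs = agreement.match_beats(
                ibis[tag_a], ibis[tag_b], tolerance_ms=config.match_tolerance_ms
            )
            ba = agreement.bland_altman(pairs)
            fit = agreement.linear_fit(pairs.ibi_a, pairs.ibi_b)
        except ValueError as exc:
            raise RuntimeError(
                f"agreement stage failed for pair {tag_a}/{tag_b}: {exc}"
            ) from exc
        pair_key = f"{tag_a}_vs_{tag_b}"
        windowed = {
            f"r_squared_{w:g}s": _windowed_r2(ibis[tag_a], ibis[tag_b], w)
            for w in config.window_averages_s
        }
        report["pairs"][pair_key] = {
            "n_pairs": len(pairs),
            "lag_s": pairs.lag_s,
            "bland_altman": asdict(ba),
            "regression": asdict(fit),
            "r_squared_beat": fit.r_squared,
            **windowed,
        }
        np.savetxt(
            outdir / f"{pair_key}_pairs.csv",
            np.column_stack([pairs.beat_times, pairs.ibi_a, pairs.ibi_b]),
            delimiter=",",
            header="time_s,ibi_a_ms,ibi_b_ms",
            comments="",
        )
        if config.make_plots:
            agreement.bland_altman_plot(pairs, ba, outdir / f"{pair_key}_ba.png")
            agreement.scatter_plot(
                pairs.ibi_a, pairs.ibi_b, fit, outdir / f"{pair_key}_scatter.png"
            )

    if hrv_tables:
        import pandas as pd

        pd.concat(hrv_tables, ignore_index=True).to_csv(
            outdir / "hrv_estimates.csv", index=False, float_format="%.6g"
        )
    pcio.write_report(outdir / "report.json", report)
    logger.info("pipeline complete: %s", outdir)
    return report
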