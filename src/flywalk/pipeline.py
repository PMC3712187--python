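"""End-to-end composition: detect -> windows -> match -> link -> stats."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .detection import Detection, Frame, detect_blobs, estimate_background
from .geometry import ArenaGeometry, view_strip_boundaries
from .session import AnalysisWindow, detect_taps, extract_windows, motion_energy
from .stats import CohortSummary, cohort_summary
from .tracking import Trajectory, filter_trajectories, link_frames, match_views
from .io import detections_from_frame

__all__ = ["PipelineResult", "detect_all", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    windows: list[AnalysisWindow]
    trajectories: list[Trajectory]
    summaries: list[CohortSummary]
    detections: pd.DataFrame | None = None


def detect_all(frames: Sequence[Frame], geom: ArenaGeometry, cfg: PipelineConfig) -> list[list[Detection]]:
    """Background estimation + per-frame blob detection over a session."""
    background = estimate_background(frames, sample_step=5)
    strips = view_strip_boundaries(geom)
    out = []
    for f in frames:
        out.append(
            detect_blobs(
                f,
                background,
                min_area=cfg["detection.min_area"],
                threshold=cfg.detection_threshold,
                strip_boundaries=strips,
            )
        )
    return out


def run_pipeline(
    *,
    frames: Sequence[Frame] | None = None,
    detections: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
    windows: Sequence[AnalysisWindow] | None = None,
    cohort: str = "",
    age_days: float = 0.0,
) -> PipelineResult:
    """Run the full analysis from frames or a pre-extracted detections table.

    With frames, the analysis windows are found automatically from the
    motion-energy trace; with a detections table (detection stage skipped)
    the windows must be supplied, or the whole recording is analysed as a
    single window.  Trajectories are linked per window so every output is
    traceable to one post-tap climbing period.
    """
    if (frames is None) == (detections is None):
        raise ValueError("provide exactly one of frames or detections")
    cfg = config or PipelineConfig()
    geom = cfg.arena()

    if frames is not None:
        trace = motion_energy(frames)
        taps = detect_taps(
            trace, k=cfg["session.energy_k"], min_separation=cfg["session.min_separation_s"]
        )
        session_end = frames[-1].time
        auto_windows = extract_windows(
            taps, duration=cfg["session.window_s"], session_end=session_end
        )
        windows = list(windows) if windows is not None else auto_windows
        per_frame = detect_all(frames, geom, cfg)
        times = [f.time for f in frames]
        log.info("detected %d blobs over %d frames", sum(map(len, per_frame)), len(frames))
    else:
        per_frame = detections_from_frame(detections)
        times = [ds[0].time for ds in per_frame if ds]
        if windows is None:
            end = times[-1] if times else 0.0
            windows = [AnalysisWindow(label="all", start=0.0, duration=end + 1e-9)]
        else:
            windows = list(windows)

    trajectories: list[Trajectory] = []
    for w in windows:
        in_window = [
            ds for ds, t in zip(per_frame, times) if ds and w.contains(t)
        ]
        cand_frames = [match_views(ds, geom) for ds in in_window]
        trajs = link_frames(
            cand_frames, gate=cfg["tracking.gate_mm"], max_gap=cfg["tracking.max_gap"]
        )
        for t in trajs:
            t.id = len(trajectories)
            t.meta["window"] = w.label
            trajectories.append(t)
        log.info(
            "window %s: %d candidate frames, %d trajectories", w.label, len(in_window), len(trajs)
        )

    trajectories = filter_trajectories(trajectories, min_samples=3)
    bins = np.linspace(
        cfg["stats.hist_min"], cfg["stats.hist_max"], cfg["stats.hist_bins"] + 1
    )
    summaries = []
    if trajectories:
        summaries.append(
            cohort_summary(trajectories, cohort=cohort, age_days=age_days, bins=bins)
        )
    else:
        log.info("no trajectories survived filtering; zero cohorts summarised")
    return PipelineResult(windows=list(windows), trajectories=trajectories, summaries=summaries)
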