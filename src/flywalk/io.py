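"""Readers and writers for the pipeline's file dialects.

All tables are UTF-8 CSV with header rows and '.' decimals; times are in
seconds from session start, positions in mm, units embedded in the column
names.  Frames are read from a directory of PNG/TIFF images named by frame
index; analysis windows are JSON.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .detection import Detection, Frame
from .geometry import View
from .session import AnalysisWindow
from .stats import CohortSummary
from .tracking import Trajectory

__all__ = [
    "write_trajectories", "read_trajectories",
    "write_detections", "read_detections",
    "detections_from_frame", "windows_to_json", "windows_from_json",
    "write_windows", "read_windows",
    "write_cohort_stats", "write_histograms",
    "read_frames_dir", "write_frames_dir",
]

TRAJECTORY_COLUMNS = ["traj_id", "time_s", "x_mm", "y_mm", "z_mm"]
DETECTION_COLUMNS = [
    "frame", "time_s", "view", "u_px", "v_px", "area_px2",
    "bbox_x", "bbox_y", "bbox_w", "bbox_h",
]


def write_trajectories(trajs: Sequence[Trajectory], path: str | Path) -> None:
    """Write trajectories sorted by (traj_id, time_s), one row per sample."""
    rows = []
    for t in trajs:
        for i in range(len(t)):
            rows.append((t.id, t.times[i], *t.positions[i]))
    df = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    df = df.sort_values(["traj_id", "time_s"], kind="stable")
    # %.17g round-trips IEEE doubles: the written CSV is lossless
    df.to_csv(path, index=False, float_format="%.17g")


def read_trajectories(path: str | Path) -> list[Trajectory]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    trajs = []
    for tid, g in df.groupby("traj_id", sort=True):
        trajs.append(
            Trajectory(
                id=int(tid),
                times=g["time_s"].to_numpy(),
                positions=g[["x_mm", "y_mm", "z_mm"]].to_numpy(),
            )
        )
    return trajs


def detections_from_frame(df: pd.DataFrame) -> list[list[Detection]]:
    """Convert a detections table into per-frame Detection lists."""
    missing = set(DETECTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detections table missing columns: {sorted(missing)}")
    frames = []
    for _, g in df.groupby("frame", sort=True):
        frames.append(
            [
                Detection(
                    frame_index=int(r.frame),
                    time=float(r.time_s),
                    view=View(r.view),
                    centroid=(float(r.u_px), float(r.v_px)),
                    area=int(r.area_px2),
                    bbox=(int(r.bbox_x), int(r.bbox_y), int(r.bbox_w), int(r.bbox_h)),
                )
                for r in g.itertuples()
            ]
        )
    return frames


def write_detections(detections: Iterable[Detection] | pd.DataFrame, path: str | Path) -> None:
    if isinstance(detections, pd.DataFrame):
        df = detections[DETECTION_COLUMNS]
    else:
        df = pd.DataFrame(
            [
                (
                    d.frame_index, d.time, d.view.value, d.centroid[0], d.centroid[1],
                    d.area, *d.bbox,
                )
                for d in detections
            ],
            columns=DETECTION_COLUMNS,
        )
    df.to_csv(path, index=False, float_format="%.17g")


def read_detections(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(DETECTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detections CSV missing columns: {sorted(missing)}")
    return df


def windows_to_json(windows: Sequence[AnalysisWindow]) -> list[dict]:
    return [
        {"label": w.label, "start_s": w.start, "duration_s": w.duration} for w in windows
    ]


def windows_from_json(data: Sequence[dict]) -> list[AnalysisWindow]:
    return [
        AnalysisWindow(label=d["label"], start=float(d["start_s"]), duration=float(d["duration_s"]))
        for d in data
    ]


def write_windows(windows: Sequence[AnalysisWindow], path: str | Path) -> None:
    Path(path).write_text(json.dumps(windows_to_json(windows), indent=2) + "\n")


def read_windows(path: str | Path) -> list[AnalysisWindow]:
    return windows_from_json(json.loads(Path(path).read_text()))


def write_cohort_stats(summaries: Sequence[CohortSummary], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "cohort": s.cohort,
                "age_days": s.age_days,
                "n_traj": s.n_trajectories,
                "mean_speed_mms": s.mean_speed,
                "max_speed_mms": s.mean_max_speed,
                "mean_persistence": s.mean_persistence,
                "mean_turn_tightness": s.mean_turn_tightness,
            }
            for s in summaries
        ]
    )
    df.to_csv(path, index=False)


def write_histograms(summaries: Sequence[CohortSummary], path: str | Path) -> None:
    rows = []
    for s in summaries:
        for i in range(len(s.hist_density)):
            rows.append(
                {
                    "cohort": s.cohort,
                    "age_days": s.age_days,
                    "bin_left": s.hist_edges[i],
                    "bin_right": s.hist_edges[i + 1],
                    "density": s.hist_density[i],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


_FRAME_RE = re.compile(r"(\d+)\.(png|tif|tiff)$", re.IGNORECASE)


def read_frames_dir(path: str | Path, fps: float = 10.0) -> list[Frame]:
    """Read a directory of PNG/TIFF frames named by index.

    Frame times are index/fps; colour images are converted to grayscale by
    channel averaging.
    """
    path = Path(path)
    entries = []
    for p in sorted(path.iterdir()):
        m = _FRAME_RE.search(p.name)
        if m:
            entries.append((int(m.group(1)), p))
    if not entries:
        raise FileNotFoundError(f"no indexed PNG/TIFF frames found in {path}")
    entries.sort()
    frames = []
    for idx, p in entries:
        img = np.asarray(iio.imread(p))
        if img.ndim == 3:
            img = img.mean(axis=2)
        frames.append(Frame(index=idx, time=idx / fps, pixels=img))
    return frames


def write_frames_dir(frames: Sequence[Frame], path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for f in frames:
        img = np.asarray(f.pixels)
        if img.dtype != np.uint8:
            img = np.clip(img, 0, 255).astype(np.uint8)
        iio.imwrite(path / f"{f.index:06d}.png", img)
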