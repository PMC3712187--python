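"""Tap detection and analysis-window extraction.

A recording session lasts 90 s: the tube of flies is dropped into the
apparatus (tap at t0) and briefly lifted and dropped again 30 s and 60 s
later.  Each tap knocks the flies to the tube floor and elicits negative
geotaxis — vigorous upward walking — which is analysed over a 15 s window
starting when the flies have just landed.

Taps are found from the motion-energy trace (mean absolute intensity
difference between consecutive frames): the whole-field shake of a tap
dwarfs the energy of normal fly motion.  Frames whose energy exceeds
``k`` times the median energy are grouped into runs; each run is one tap,
timed at the run's last frame so that the window starts once the
disturbance has settled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .detection import Frame

__all__ = ["MotionEnergyTrace", "AnalysisWindow", "motion_energy", "detect_taps", "extract_windows"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MotionEnergyTrace:
    """Per-frame-pair motion energy; ``times`` are the later frame's times."""

    energy: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "energy", np.asarray(self.energy, dtype=float))
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if len(self.energy) != len(self.times):
            raise ValueError("energy and times length mismatch")
        if np.any(self.energy < 0):
            raise ValueError("motion energy must be non-negative")


@dataclass(frozen=True)
class AnalysisWindow:
    """One 15 s post-tap analysis window."""

    label: str
    start: float
    duration: float

    @property
    def end(self) -> float:
        return self.start + self.duration

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end


def motion_energy(frames: Sequence[Frame]) -> MotionEnergyTrace:
    """Mean absolute intensity difference between consecutive frames.

    Invariant to global additive intensity offsets between sessions.
    """
    frames = list(frames)
    if len(frames) < 2:
        raise ValueError("motion energy needs at least 2 frames")
    energy = np.empty(len(frames) - 1)
    times = np.empty(len(frames) - 1)
    prev = np.asarray(frames[0].pixels, dtype=np.float32)
    for i, f in enumerate(frames[1:]):
        cur = np.asarray(f.pixels, dtype=np.float32)
        energy[i] = float(np.mean(np.abs(cur - prev)))
        times[i] = f.time
        prev = cur
    return MotionEnergyTrace(energy=energy, times=times)


def detect_taps(
    trace: MotionEnergyTrace, k: float = 5.0, *, min_separation: float = 5.0
) -> list[float]:
    """Tap times from a motion-energy trace.

    Frames with energy strictly above ``k * median(energy)`` form
    high-energy runs; runs closer than ``min_separation`` seconds are
    merged (one tap disturbance).  The tap time is the last frame of each
    run — the moment the flies have just landed at the tube bottom.
    """
    if len(trace.energy) == 0:
        raise ValueError("empty motion-energy trace")
    threshold = k * float(np.median(trace.energy))
    above = np.flatnonzero(trace.energy > threshold)
    if len(above) == 0:
        return []
    taps = []
    run_end = above[0]
    for idx in above[1:]:
        if trace.times[idx] - trace.times[run_end] >= min_separation:
            taps.append(float(trace.times[run_end]))
            run_end = idx
        else:
            run_end = idx
    taps.append(float(trace.times[run_end]))
    return taps


def extract_windows(
    taps: Sequence[float],
    duration: float = 15.0,
    *,
    session_end: float | None = None,
) -> list[AnalysisWindow]:
    """One analysis window per tap, starting at the tap, labelled t0, t1, ...

    Windows are clipped at the next tap (with a warning) and at the session
    end when given.  A window of zero length (tap at the very end of the
    session) is returned with duration 0 and flagged in the log.
    """
    if duration <= 0:
        raise ValueError("window duration must be positive")
    taps = sorted(float(t) for t in taps)
    windows = []
    for i, start in enumerate(taps):
        d = duration
        if i + 1 < len(taps) and taps[i + 1] < start + d:
            d = taps[i + 1] - start
            log.warning(
                "window t%d truncated to %.2f s by the next tap at %.2f s", i, d, taps[i + 1]
            )
        if session_end is not None and start + d > session_end:
            d = max(0.0, session_end - start)
        if d <= 0:
            log.warning("window t%d at %.2f s has zero length", i, start)
        windows.append(AnalysisWindow(label=f"t{i}", start=start, duration=d))
    return windows
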