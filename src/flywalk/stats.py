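"""Locomotor descriptors and cohort-level statistics.

Three descriptors summarise each walking trajectory:

* **speed** — distance moved between consecutive frames divided by the
  elapsed time, in mm/s;
* **persistence length** — the ratio of the end-to-end distance of the
  trajectory to the total distance travelled, in [0, 1] (1 = perfectly
  straight path);
* **turn tightness** — the median dot product of adjacent unit step
  vectors, in [-1, 1] (1 = straight, 0 = right-angle turns,
  -1 = reversals).  Step vectors are normalised by default so the
  descriptor is the cosine of the turning angle and is speed-invariant;
  the raw (unnormalised) variant is available via a flag.

Cohort summaries pool these descriptors over the trajectories of one
genotype at one age: a density-normalised speed histogram over 0-20 mm/s,
the mean speed over all steps, and the cohort mean of per-trajectory
"maximum" (95th-percentile) speed — robust to single-frame triangulation
glitches.  Progressive impairment is quantified by the least-squares slope
of cohort mean speed against age (the decline rate) and by the fractional
signal difference between a test cohort and its age-matched control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .tracking import Trajectory

__all__ = [
    "TrajectoryStats",
    "CohortSummary",
    "speeds",
    "persistence_length",
    "turn_tightness",
    "trajectory_stats",
    "speed_histogram",
    "cohort_summary",
    "decline_rate",
    "fractional_signal_difference",
    "compare_groups",
]

DEFAULT_HIST_RANGE = (0.0, 20.0)
DEFAULT_HIST_BINS = 40


def speeds(traj: Trajectory) -> np.ndarray:
    """Per-step speeds in mm/s."""
    dt = np.diff(traj.times)
    if np.any(dt <= 0):
        raise ValueError("duplicate or decreasing timestamps")
    steps = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1)
    return steps / dt


def persistence_length(traj: Trajectory) -> float | None:
    """End-to-end distance over total path length, in [0, 1].

    Returns ``None`` (undefined) when the total distance is zero; such
    trajectories are excluded from cohort means.
    """
    steps = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1)
    total = float(steps.sum())
    if total == 0.0:
        return None
    end_to_end = float(np.linalg.norm(traj.positions[-1] - traj.positions[0]))
    return min(end_to_end / total, 1.0)


def turn_tightness(traj: Trajectory, *, normalized: bool = True) -> float | None:
    """Median dot product of adjacent step vectors.

    With ``normalized=True`` (default) the step vectors are unit-normalised
    so the value is the cosine of the turning angle, bounded in [-1, 1].
    Zero-length steps are skipped; returns ``None`` when fewer than two
    non-zero steps remain.
    """
    if len(traj) < 3:
        return None
    vecs = np.diff(traj.positions, axis=0)
    norms = np.linalg.norm(vecs, axis=1)
    vecs = vecs[norms > 0]
    norms = norms[norms > 0]
    if len(vecs) < 2:
        return None
    if normalized:
        vecs = vecs / norms[:, None]
    dots = np.einsum("ij,ij->i", vecs[:-1], vecs[1:])
    if normalized:
        dots = np.clip(dots, -1.0, 1.0)  # guard rounding past the cosine bounds
    return float(np.median(dots))


@dataclass(frozen=True)
class TrajectoryStats:
    """Per-trajectory locomotor descriptors."""

    speeds: np.ndarray
    mean_speed: float
    median_speed: float
    max_speed: float
    persistence_length: float | None
    turn_tightness: float | None
    n_steps: int


def trajectory_stats(traj: Trajectory, *, max_speed_percentile: float = 95.0) -> TrajectoryStats:
    s = speeds(traj)
    return TrajectoryStats(
        speeds=s,
        mean_speed=float(s.mean()),
        median_speed=float(np.median(s)),
        max_speed=float(np.percentile(s, max_speed_percentile)),
        persistence_length=persistence_length(traj),
        turn_tightness=turn_tightness(traj),
        n_steps=len(s),
    )


def speed_histogram(
    values: Sequence[float],
    bins: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Density-normalised speed histogram; overflow goes into the last bin.

    Default edges span 0-20 mm/s in 40 bins.  Returns ``(edges, density)``
    with the density integrating to exactly 1.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty speed sample")
    if bins is None:
        bins = np.linspace(*DEFAULT_HIST_RANGE, DEFAULT_HIST_BINS + 1)
    bins = np.asarray(bins, dtype=float)
    # clip into range so out-of-range speeds accumulate in the edge bins
    eps = 1e-9 * (bins[-1] - bins[0])
    clipped = np.clip(values, bins[0], bins[-1] - eps)
    density, edges = np.histogram(clipped, bins=bins, density=True)
    return edges, density


@dataclass(frozen=True)
class CohortSummary:
    """Distributional locomotor statistics of one genotype at one age."""

    cohort: str
    age_days: float
    hist_edges: np.ndarray
    hist_density: np.ndarray
    mean_speed: float
    mean_max_speed: float
    mean_persistence: float | None
    mean_turn_tightness: float | None
    n_trajectories: int
    n_steps: int


def cohort_summary(
    trajs: Sequence[Trajectory],
    *,
    cohort: str = "",
    age_days: float = 0.0,
    bins: np.ndarray | None = None,
) -> CohortSummary:
    """Pool per-trajectory descriptors into a cohort summary.

    The mean speed pools all steps of all trajectories; the "maximum
    velocity" statistic is the cohort mean of each trajectory's
    95th-percentile speed.  Undefined persistence/tightness values are
    excluded from their means but the trajectories still count toward
    ``n_trajectories``.
    """
    trajs = list(trajs)
    if not trajs:
        raise ValueError("cohort_summary needs at least one trajectory")
    all_stats = [trajectory_stats(t) for t in trajs]
    pooled = np.concatenate([st.speeds for st in all_stats])
    edges, density = speed_histogram(pooled, bins=bins)
    pers = [st.persistence_length for st in all_stats if st.persistence_length is not None]
    turns = [st.turn_tightness for st in all_stats if st.turn_tightness is not None]
    return CohortSummary(
        cohort=cohort,
        age_days=age_days,
        hist_edges=edges,
        hist_density=density,
        mean_speed=float(pooled.mean()),
        mean_max_speed=float(np.mean([st.max_speed for st in all_stats])),
        mean_persistence=float(np.mean(pers)) if pers else None,
        mean_turn_tightness=float(np.mean(turns)) if turns else None,
        n_trajectories=len(trajs),
        n_steps=int(pooled.size),
    )


def decline_rate(summaries: Sequence[CohortSummary]) -> float:
    """Least-squares slope of cohort mean speed against age, mm/s per day."""
    summaries = list(summaries)
    ages = np.array([s.age_days for s in summaries], dtype=float)
    if len(np.unique(ages)) < 3:
        raise ValueError("decline_rate needs summaries at >= 3 distinct ages")
    means = np.array([s.mean_speed for s in summaries], dtype=float)
    slope, _ = np.polyfit(ages, means, 1)
    return float(slope)


_METRICS = {
    "mean_speed": "mean_speed",
    "max_speed": "mean_max_speed",
    "persistence": "mean_persistence",
    "turn_tightness": "mean_turn_tightness",
}


def fractional_signal_difference(
    control: CohortSummary, test: CohortSummary, metric: str = "mean_speed"
) -> float:
    """(control - test) / control for the chosen cohort metric.

    Positive when the test cohort is impaired relative to control; negative
    values (test faster than control) are allowed.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    if control.age_days != test.age_days:
        raise ValueError("cohorts must be age-matched")
    c = getattr(control, _METRICS[metric])
    t = getattr(test, _METRICS[metric])
    if c is None or t is None:
        raise ValueError(f"metric {metric!r} undefined for one of the cohorts")
    if c == 0:
        raise ValueError("control metric is zero; fractional difference undefined")
    return (c - t) / c


def compare_groups(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of per-trajectory metrics.

    The trajectory is the unit of replication; pass per-trajectory mean
    speeds (or another descriptor) for the two cohorts.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")
    res = sps.ranksums(a, b)
    return float(res.statistic), float(res.pvalue)
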