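"""Cross-view matching and frame-to-frame linking into 3D trajectories.

Per frame, detections from the three views are back-projected to rays and
triangulated pairwise; every cross-view pair or triple whose best ray pair
crosses within the tolerance becomes a candidate.  Conflicts (a detection
claimed by several candidates) are resolved globally: the accepted set of
candidates maximises the number of detections explained (so three-view
candidates beat two-view ones built from their parts) and, among such sets,
minimises the total crossing distance.  This is an exact set-packing solved
with a small integer program; when no detection is contested the feasible
candidates are accepted directly.

Linking is optimal one-to-one assignment between active trajectory heads
and the current frame's candidates with Euclidean displacement cost, with
assignments above the 2 mm gate forbidden.  The gate excludes flying and
falling flies, whose frame-to-frame motion is faster than walking.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import LinearConstraint, linear_sum_assignment, milp
from scipy.optimize import Bounds

from .detection import Detection
from .geometry import ArenaGeometry, Ray, View, pixel_to_ray

__all__ = [
    "Candidate3D",
    "Trajectory",
    "match_views",
    "link_frames",
    "filter_trajectories",
    "group_candidates_by_frame",
]

# Reward per detection explained by an accepted candidate; dominates any
# achievable sum of crossing distances (each <= tolerance <= a few mm).
_VIEW_REWARD = 1.0e3


@dataclass(frozen=True)
class Candidate3D:
    """A triangulated fly position in one frame."""

    frame_index: int
    time: float
    position: np.ndarray
    n_views: int
    min_pair_distance: float
    detection_indices: tuple[int, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))


@dataclass
class Trajectory:
    """Time-stamped Cartesian positions of a single fly."""

    id: int
    times: np.ndarray
    positions: np.ndarray  # (n, 3) mm
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions length mismatch")
        if len(self.times) < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def displacements(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)


def _inside_volume(p: np.ndarray, geom: ArenaGeometry, margin: float) -> bool:
    r = float(np.hypot(p[0], p[1]))
    return (
        r <= geom.tube_radius + margin
        and -margin <= p[2] <= geom.tube_height + margin
    )


def _pairwise_closest(rays_a: list[Ray], rays_b: list[Ray]):
    """Vectorised line-line closest approach: distance and midpoint matrices."""
    o1 = np.array([r.origin for r in rays_a])
    d1 = np.array([r.direction for r in rays_a])
    o2 = np.array([r.origin for r in rays_b])
    d2 = np.array([r.direction for r in rays_b])
    b = d1 @ d2.T
    w0 = o1[:, None, :] - o2[None, :, :]
    d = np.einsum("abk,ak->ab", w0, d1)
    e = np.einsum("abk,bk->ab", w0, d2)
    denom = 1.0 - b * b
    parallel = denom < 1e-12
    safe = np.where(parallel, 1.0, denom)
    t1 = np.where(parallel, -d, (b * e - d) / safe)
    t2 = np.where(parallel, 0.0, (e - b * d) / safe)
    p1 = o1[:, None, :] + t1[..., None] * d1[:, None, :]
    p2 = o2[None, :, :] + t2[..., None] * d2[None, :, :]
    dist = np.linalg.norm(p1 - p2, axis=-1)
    mid = 0.5 * (p1 + p2)
    return dist, mid


def _enumerate_combos(
    rays_by_view: dict[View, list[tuple[int, Ray]]],
    geom: ArenaGeometry,
    tol: float,
    margin: float,
):
    """All feasible cross-view pairs/triples: (det_indices, n_views, dist, point).

    A combination is feasible when its best ray pair crosses within ``tol``
    (two of three suffice) and the triangulated point lies in the tube
    volume plus margin.
    """
    views = [v for v in (View.DIRECT, View.LEFT, View.RIGHT) if rays_by_view.get(v)]
    idxs = {v: [i for i, _ in rays_by_view[v]] for v in views}
    rays = {v: [r for _, r in rays_by_view[v]] for v in views}
    pair_dist: dict[tuple[View, View], np.ndarray] = {}
    pair_mid: dict[tuple[View, View], np.ndarray] = {}
    for va, vb in itertools.combinations(views, 2):
        pair_dist[(va, vb)], pair_mid[(va, vb)] = _pairwise_closest(rays[va], rays[vb])

    combos = []
    for (va, vb), dmat in pair_dist.items():
        mids = pair_mid[(va, vb)]
        for i, j in np.argwhere(dmat <= tol):
            point = mids[i, j]
            if _inside_volume(point, geom, margin):
                combos.append(((idxs[va][i], idxs[vb][j]), 2, float(dmat[i, j]), point))

    if len(views) == 3:
        # A 3-view candidate needs a mutually consistent triple: at least
        # two of its three ray pairs must cross within tolerance, otherwise
        # it is just a 2-view candidate plus an unrelated detection.
        va, vb, vc = views
        ok_ab = (pair_dist[(va, vb)] <= tol)[:, :, None]
        ok_ac = (pair_dist[(va, vc)] <= tol)[:, None, :]
        ok_bc = (pair_dist[(vb, vc)] <= tol)[None, :, :]
        n_ok = ok_ab.astype(np.int8) + ok_ac.astype(np.int8) + ok_bc.astype(np.int8)
        for i, j, k in np.argwhere(n_ok >= 2):
            d3 = np.array(
                [
                    pair_dist[(va, vb)][i, j],
                    pair_dist[(va, vc)][i, k],
                    pair_dist[(vb, vc)][j, k],
                ]
            )
            m3 = np.array(
                [
                    pair_mid[(va, vb)][i, j],
                    pair_mid[(va, vc)][i, k],
                    pair_mid[(vb, vc)][j, k],
                ]
            )
            within = d3 <= tol
            point = m3[within].mean(axis=0)
            if _inside_volume(point, geom, margin):
                combos.append(
                    ((idxs[va][i], idxs[vb][j], idxs[vc][k]), 3, float(d3.min()), point)
                )
    return combos


def _combo_costs(combos, indices):
    # minimise dist - reward*n_views; tiny index epsilon breaks ties
    # deterministically toward the lexicographically first combination
    return {ci: combos[ci][2] - _VIEW_REWARD * combos[ci][1] + 1e-9 * ci for ci in indices}


def _select_exhaustive(combos, component):
    """Exact search over conflict-free subsets of one conflict component."""
    costs = _combo_costs(combos, component)
    best_cost = math.inf
    best_sel: tuple[int, ...] = ()

    def recurse(pos, used, sel, cost):
        nonlocal best_cost, best_sel
        if pos == len(component):
            if cost < best_cost:
                best_cost = cost
                best_sel = tuple(sel)
            return
        ci = component[pos]
        dets = combos[ci][0]
        if not used.intersection(dets):
            recurse(pos + 1, used | set(dets), sel + [ci], cost + costs[ci])
        recurse(pos + 1, used, sel, cost)

    recurse(0, frozenset(), [], 0.0)
    return list(best_sel)


def _select_milp(combos, component):
    """Exact set-packing on one component via an integer program."""
    costs = _combo_costs(combos, component)
    c = np.array([costs[ci] for ci in component])
    dets = sorted({d for ci in component for d in combos[ci][0]})
    det_row = {d: i for i, d in enumerate(dets)}
    A = np.zeros((len(dets), len(component)))
    for col, ci in enumerate(component):
        for d in combos[ci][0]:
            A[det_row[d], col] = 1.0
    res = milp(
        c,
        constraints=LinearConstraint(A, -np.inf, 1.0),
        integrality=np.ones(len(component)),
        bounds=Bounds(0.0, 1.0),
    )
    if not res.success:  # pragma: no cover - HiGHS handles these sizes
        raise RuntimeError(f"view-matching assignment failed: {res.message}")
    return [ci for col, ci in enumerate(component) if res.x[col] > 0.5]


def _select_combos(combos):
    """Exact conflict-free selection maximising explained detections then
    minimising total crossing distance.

    The conflict graph (combos sharing a detection) is split into connected
    components; each component is solved exactly — small ones by exhaustive
    search, large ones as an integer program.
    """
    if not combos:
        return []
    det_usage: dict[int, list[int]] = {}
    for ci, (idxs, *_rest) in enumerate(combos):
        for d in idxs:
            det_usage.setdefault(d, []).append(ci)

    # union-find over combos sharing detections
    parent = list(range(len(combos)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for users in det_usage.values():
        for ci in users[1:]:
            ra, rb = find(users[0]), find(ci)
            if ra != rb:
                parent[rb] = ra

    components: dict[int, list[int]] = {}
    for ci in range(len(combos)):
        components.setdefault(find(ci), []).append(ci)

    chosen: list[int] = []
    for comp in components.values():
        if len(comp) == 1:
            chosen.extend(comp)
        elif len(comp) <= 16:
            chosen.extend(_select_exhaustive(combos, comp))
        else:
            chosen.extend(_select_milp(combos, comp))
    return sorted(chosen)


def match_views(
    detections: Sequence[Detection],
    geom: ArenaGeometry,
    tol: float | None = None,
    *,
    volume_margin: float = 2.0,
) -> list[Candidate3D]:
    """Triangulate one frame's detections into 3D candidates.

    All detections must come from the same frame.  Candidates whose
    position falls outside the tube volume plus ``volume_margin`` are
    discarded as triangulation ghosts.
    """
    if not detections:
        return []
    frame_indices = {d.frame_index for d in detections}
    if len(frame_indices) != 1:
        raise ValueError("match_views expects detections from a single frame")
    frame_index = frame_indices.pop()
    time = detections[0].time
    if tol is None:
        tol = geom.crossing_tolerance

    rays_by_view: dict[View, list[tuple[int, Ray]]] = {}
    for i, det in enumerate(detections):
        ray = pixel_to_ray(det.centroid, det.view, geom)
        rays_by_view.setdefault(det.view, []).append((i, ray))

    combos = _enumerate_combos(rays_by_view, geom, tol, volume_margin)
    combos.sort(key=lambda c: c[0])
    chosen = _select_combos(combos)
    candidates = []
    for ci in chosen:
        idxs, k, dist, point = combos[ci]
        candidates.append(
            Candidate3D(
                frame_index=frame_index,
                time=time,
                position=point,
                n_views=k,
                min_pair_distance=dist,
                detection_indices=idxs,
            )
        )
    return candidates


def group_candidates_by_frame(candidates: Iterable[Candidate3D]) -> list[list[Candidate3D]]:
    """Group a flat candidate list into per-frame lists in time order."""
    by_frame: dict[int, list[Candidate3D]] = {}
    for c in candidates:
        by_frame.setdefault(c.frame_index, []).append(c)
    return [by_frame[k] for k in sorted(by_frame)]


class _Track:
    __slots__ = ("tid", "times", "positions", "misses")

    def __init__(self, tid, time, position):
        self.tid = tid
        self.times = [time]
        self.positions = [position]
        self.misses = 0


def link_frames(
    frames: Sequence[Sequence[Candidate3D]],
    gate: float = 2.0,
    *,
    max_gap: int = 0,
) -> list[Trajectory]:
    """Link per-frame candidates into single-fly trajectories.

    One-to-one optimal assignment per frame between active trajectory heads
    and candidates, displacement cost, assignments above ``gate`` (mm)
    forbidden.  Unmatched candidates open new trajectories; trajectories
    unmatched for more than ``max_gap`` consecutive frames are closed.
    Only trajectories with at least 2 samples are returned, and every
    consecutive displacement is at most ``gate`` by construction.
    """
    if gate <= 0:
        raise ValueError("gate must be positive")
    BIG = 1e12
    active: list[_Track] = []
    closed: list[_Track] = []
    next_id = 0
    last_time = None

    for cands in frames:
        cands = list(cands)
        if cands:
            t = cands[0].time
            if last_time is not None and t <= last_time:
                raise ValueError("frame times must be strictly increasing")
            last_time = t
        matched_tracks: set[int] = set()
        matched_cands: set[int] = set()
        if active and cands:
            cost = np.full((len(active), len(cands)), BIG)
            for i, tr in enumerate(active):
                head = tr.positions[-1]
                for j, c in enumerate(cands):
                    d = float(np.linalg.norm(c.position - head))
                    if d <= gate:
                        cost[i, j] = d
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if cost[i, j] < BIG:
                    tr = active[i]
                    tr.times.append(cands[j].time)
                    tr.positions.append(cands[j].position)
                    tr.misses = 0
                    matched_tracks.add(i)
                    matched_cands.add(j)
        still_active = []
        for i, tr in enumerate(active):
            if i in matched_tracks:
                still_active.append(tr)
            else:
                tr.misses += 1
                if tr.misses > max_gap:
                    closed.append(tr)
                else:
                    still_active.append(tr)
        active = still_active
        for j, c in enumerate(cands):
            if j not in matched_cands:
                active.append(_Track(next_id, c.time, c.position))
                next_id += 1
    closed.extend(active)

    trajectories = []
    for tr in sorted(closed, key=lambda t: t.tid):
        if len(tr.times) < 2:
            continue
        traj = Trajectory(id=tr.tid, times=np.array(tr.times), positions=np.array(tr.positions))
        assert traj.displacements.max() <= gate + 1e-12
        trajectories.append(traj)
    # renumber densely but stably
    for new_id, traj in enumerate(trajectories):
        traj.id = new_id
    return trajectories


def filter_trajectories(trajs: Sequence[Trajectory], min_samples: int) -> list[Trajectory]:
    """Keep trajectories with at least ``min_samples`` samples."""
    if min_samples < 2:
        raise ValueError("min_samples must be >= 2")
    return [t for t in trajs if len(t) >= min_samples]
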