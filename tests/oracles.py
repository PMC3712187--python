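"""Independent brute-force oracles for assignment problems.

These deliberately re-derive the matching/linking optima by exhaustive
enumeration, sharing no code with the implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np

VIEW_REWARD = 1.0e3  # must dominate any sum of crossing distances


def line_pair_distance(o1, d1, o2, d2):
    """Scalar closest-approach distance between two lines (independent formula)."""
    n = np.cross(d1, d2)
    w = np.asarray(o1) - np.asarray(o2)
    nn = np.linalg.norm(n)
    if nn < 1e-9:  # parallel
        return float(np.linalg.norm(w - (w @ d1) * np.asarray(d1)))
    return float(abs(w @ n) / nn)


def line_pair_midpoint(o1, d1, o2, d2):
    """Closest-approach midpoint via least squares (independent route)."""
    A = np.column_stack([np.asarray(d1), -np.asarray(d2)])
    b = np.asarray(o2) - np.asarray(o1)
    (t1, t2), *_ = np.linalg.lstsq(A, b, rcond=None)
    return 0.5 * (np.asarray(o1) + t1 * np.asarray(d1) + np.asarray(o2) + t2 * np.asarray(d2))


def enumerate_feasible_combos(rays_by_view, tol, is_valid_point=None):
    """All cross-view pairs/triples feasible for matching.

    Pairs need their crossing distance within ``tol``; triples need at
    least two of their three pairwise crossings within ``tol``; the
    triangulated point (pair midpoint, or mean of within-tolerance pair
    midpoints for triples) must satisfy ``is_valid_point`` when given.
    Returns ``(det_indices, n_views, min_pair_distance)`` tuples.
    """
    views = sorted(rays_by_view)
    combos = []
    for k in (2, 3):
        for vs in itertools.combinations(views, k):
            for picks in itertools.product(*(rays_by_view[v] for v in vs)):
                idxs = tuple(i for i, _ in picks)
                rays = [r for _, r in picks]
                pairs = list(itertools.combinations(rays, 2))
                dists = [
                    line_pair_distance(a.origin, a.direction, b.origin, b.direction)
                    for a, b in pairs
                ]
                n_within = sum(d <= tol for d in dists)
                if not ((k == 2 and n_within == 1) or (k == 3 and n_within >= 2)):
                    continue
                mids = [
                    line_pair_midpoint(a.origin, a.direction, b.origin, b.direction)
                    for a, b in pairs
                ]
                point = np.mean(
                    [m for m, d in zip(mids, dists) if d <= tol], axis=0
                )
                if is_valid_point is not None and not is_valid_point(point):
                    continue
                combos.append((idxs, k, min(dists)))
    return combos


def best_packing_objective(combos):
    """Exhaustively find the optimal conflict-free packing objective.

    Minimises sum(dist - VIEW_REWARD * n_views) over conflict-free subsets;
    returns (objective, frozenset of chosen det-index tuples).
    """
    best = (0.0, frozenset())
    n = len(combos)

    def recurse(pos, used, cost, chosen):
        nonlocal best
        if cost < best[0] - 1e-12:
            best = (cost, frozenset(chosen))
        if pos == n:
            return
        for i in range(pos, n):
            idxs, k, dist = combos[i]
            if not used.intersection(idxs):
                recurse(
                    i + 1,
                    used | set(idxs),
                    cost + dist - VIEW_REWARD * k,
                    chosen | {idxs},
                )

    recurse(0, frozenset(), 0.0, frozenset())
    return best


def best_gated_assignment(prev, cand, gate):
    """Exhaustive optimal one-to-one gated assignment.

    Maximises the number of matches under the gate and, among those,
    minimises total displacement.  Returns (n_matched, total_cost).
    """
    prev = np.asarray(prev, dtype=float)
    cand = np.asarray(cand, dtype=float)
    n, m = len(prev), len(cand)
    best = (0, 0.0)
    k_max = min(n, m)
    for k in range(k_max, -1, -1):
        found = None
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(range(m), k):
                cost = 0.0
                ok = True
                for i, j in zip(rows, cols):
                    d = float(np.linalg.norm(prev[i] - cand[j]))
                    if d > gate:
                        ok = False
                        break
                    cost += d
                if ok and (found is None or cost < found):
                    found = cost
        if found is not None:
            return (k, found)
    return (0, 0.0)
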