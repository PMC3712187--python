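"""Projection and triangulation for a single-camera, two-mirror arena.

A vertical glass tube is observed by one fixed pinhole camera directly and
via two planar mirrors behind the tube.  Each mirror produces a *virtual*
view: the mirror image of a fly is, optically, the fly seen from the mirror
image of the camera.  Back-projecting a pixel from a mirror view therefore
amounts to building the ordinary camera ray through that pixel and
reflecting it about the mirror plane.

Three views of the same fly yield three rays in world coordinates.  When at
least two rays from distinct views pass within the crossing tolerance
(100 um by default) of each other, the triangulation is accepted and the 3D
position is the midpoint of the closest ray pair.

World frame convention: origin at the centre of the tube base, z up (the
gravity / climbing axis), the camera on the -y side looking along +y.
All lengths are in millimetres, angles in degrees at the API surface.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "View",
    "CameraModel",
    "MirrorPlane",
    "ArenaGeometry",
    "Ray",
    "GeometryError",
    "ProjectionError",
    "reflect_point",
    "reflect_vector",
    "project_point",
    "project_to_view",
    "pixel_to_ray",
    "ray_pair_closest",
    "triangulate",
    "TriangulationResult",
    "default_arena",
    "view_strip_boundaries",
]


class GeometryError(ValueError):
    """Invalid geometric configuration or input."""


class ProjectionError(GeometryError):
    """Point cannot be projected (at or behind the camera plane)."""


class View(str, enum.Enum):
    """Identifier of one of the three images of the tube."""

    DIRECT = "DIRECT"
    LEFT = "LEFT"
    RIGHT = "RIGHT"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _as_vec3(x) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise GeometryError(f"expected a 3-vector, got shape {v.shape}")
    return v


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise GeometryError(f"{what} has zero length")
    return v / n


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera with pose, horizontal field of view and resolution.

    Parameters
    ----------
    center : (3,) array_like
        Optical centre in world coordinates, mm.
    optical_axis : (3,) array_like
        Unit viewing direction (normalised on construction).
    up : (3,) array_like
        Unit up direction of the sensor; must be orthogonal to the axis.
    hfov : float
        Horizontal field of view, degrees, in (0, 180).
    width, height : int
        Sensor resolution in pixels.
    """

    center: np.ndarray
    optical_axis: np.ndarray
    up: np.ndarray
    hfov: float
    width: int
    height: int

    def __post_init__(self):
        object.__setattr__(self, "center", _as_vec3(self.center))
        axis = _unit(_as_vec3(self.optical_axis), "optical_axis")
        up = _unit(_as_vec3(self.up), "up")
        if abs(float(axis @ up)) > 1e-9:
            raise GeometryError("optical_axis and up must be orthogonal")
        object.__setattr__(self, "optical_axis", axis)
        object.__setattr__(self, "up", up)
        if not 0.0 < self.hfov < 180.0:
            raise GeometryError("hfov must be in (0, 180) degrees")
        if self.width <= 0 or self.height <= 0:
            raise GeometryError("sensor resolution must be positive")
        object.__setattr__(self, "_right", np.cross(axis, up))

    @property
    def right(self) -> np.ndarray:
        """Unit vector along increasing pixel column u."""
        return self._right

    @property
    def f_px(self) -> float:
        """Focal length in pixels, from the horizontal field of view."""
        return (self.width / 2.0) / math.tan(math.radians(self.hfov) / 2.0)

    @property
    def principal_point(self) -> tuple[float, float]:
        return (self.width / 2.0, self.height / 2.0)


@dataclass(frozen=True)
class MirrorPlane:
    """Oriented mirror plane producing one virtual (reflected) view."""

    point: np.ndarray
    normal: np.ndarray
    label: View

    def __post_init__(self):
        object.__setattr__(self, "point", _as_vec3(self.point))
        n = _as_vec3(self.normal)
        mag = float(np.linalg.norm(n))
        if not math.isclose(mag, 1.0, abs_tol=1e-6):
            raise GeometryError(
                f"mirror normal must be a unit vector (|n| = {mag:.6g})"
            )
        object.__setattr__(self, "normal", n / mag)
        object.__setattr__(self, "label", View(self.label))


@dataclass(frozen=True)
class Ray:
    """Half-line in world space attributed to one view."""

    origin: np.ndarray
    direction: np.ndarray
    view: View

    def __post_init__(self):
        object.__setattr__(self, "origin", _as_vec3(self.origin))
        object.__setattr__(
            self, "direction", _unit(_as_vec3(self.direction), "ray direction")
        )
        object.__setattr__(self, "view", View(self.view))


@dataclass(frozen=True)
class ArenaGeometry:
    """Complete apparatus geometry: tube, camera and the two mirrors."""

    tube_radius: float
    tube_height: float
    camera: CameraModel
    mirrors: tuple[MirrorPlane, MirrorPlane]
    crossing_tolerance: float = 0.1

    def __post_init__(self):
        if self.tube_radius <= 0 or self.tube_height <= 0:
            raise GeometryError("tube dimensions must be positive")
        if self.crossing_tolerance <= 0:
            raise GeometryError("crossing_tolerance must be positive")
        labels = {m.label for m in self.mirrors}
        if labels != {View.LEFT, View.RIGHT}:
            raise GeometryError("mirrors must be labelled LEFT and RIGHT")

    def mirror(self, view: View) -> MirrorPlane:
        view = View(view)
        for m in self.mirrors:
            if m.label == view:
                return m
        raise GeometryError(f"view {view} has no mirror")


def reflect_point(p, m: MirrorPlane) -> np.ndarray:
    """Mirror image of point ``p`` about plane ``m`` (an involution)."""
    p = _as_vec3(p)
    n = m.normal
    if not math.isclose(float(np.linalg.norm(n)), 1.0, abs_tol=1e-9):
        raise GeometryError("mirror normal must be unit length")
    return p - 2.0 * float((p - m.point) @ n) * n


def reflect_vector(v, m: MirrorPlane) -> np.ndarray:
    """Mirror image of a free vector (direction) about plane ``m``."""
    v = _as_vec3(v)
    n = m.normal
    return v - 2.0 * float(v @ n) * n


def project_point(p, cam: CameraModel) -> tuple[float, float]:
    """Project a world point to continuous (sub-pixel) pixel coordinates.

    Raises :class:`ProjectionError` if the point is not strictly in front of
    the camera.
    """
    p = _as_vec3(p)
    rel = p - cam.center
    z = float(rel @ cam.optical_axis)
    if z <= 0.0:
        raise ProjectionError("point is at or behind the camera")
    x = float(rel @ cam.right)
    y = float(rel @ -cam.up)  # v grows downward in the image
    cu, cv = cam.principal_point
    f = cam.f_px
    return (cu + f * x / z, cv + f * y / z)


def project_to_view(p, view: View, geom: ArenaGeometry) -> tuple[float, float]:
    """Pixel position of world point ``p`` in the direct or a mirror view."""
    view = View(view)
    if view is View.DIRECT:
        return project_point(p, geom.camera)
    return project_point(reflect_point(p, geom.mirror(view)), geom.camera)


def pixel_to_ray(uv: Sequence[float], view: View, geom: ArenaGeometry) -> Ray:
    """Back-project a pixel of the given view into a world-space ray.

    For the direct view this is the camera ray through the pixel.  For a
    mirror view the camera ray is reflected about the mirror plane, which is
    equivalent to the ray of the virtual (mirrored) camera through the fly.
    """
    view = View(view)
    cam = geom.camera
    u, v = float(uv[0]), float(uv[1])
    if not (-0.5 <= u <= cam.width - 0.5 and -0.5 <= v <= cam.height - 0.5):
        raise GeometryError(f"pixel ({u:.2f}, {v:.2f}) outside the sensor")
    cu, cv = cam.principal_point
    f = cam.f_px
    direction = (
        cam.optical_axis + ((u - cu) / f) * cam.right + ((v - cv) / f) * -cam.up
    )
    origin = cam.center
    if view is not View.DIRECT:
        m = geom.mirror(view)
        origin = reflect_point(origin, m)
        direction = reflect_vector(direction, m)
    return Ray(origin=origin, direction=direction, view=view)


def ray_pair_closest(r1: Ray, r2: Ray) -> tuple[float, np.ndarray]:
    """Closest approach of two rays (treated as infinite lines).

    Returns ``(distance, midpoint)`` where the midpoint bisects the common
    perpendicular segment.  Parallel rays are handled analytically: the
    distance is the perpendicular offset and the midpoint is taken between
    ``r2.origin`` and its projection onto ``r1``.
    """
    d1, d2 = r1.direction, r2.direction
    w0 = r1.origin - r2.origin
    b = float(d1 @ d2)
    denom = 1.0 - b * b
    if denom < 1e-12:
        t1 = float((r2.origin - r1.origin) @ d1)
        p1 = r1.origin + t1 * d1
        p2 = r2.origin
    else:
        d = float(d1 @ w0)
        e = float(d2 @ w0)
        t1 = (b * e - d) / denom
        t2 = (e - b * d) / denom
        p1 = r1.origin + t1 * d1
        p2 = r2.origin + t2 * d2
    return float(np.linalg.norm(p1 - p2)), 0.5 * (p1 + p2)


@dataclass(frozen=True)
class TriangulationResult:
    success: bool
    point: np.ndarray
    min_pair_distance: float


def triangulate(
    rays: Sequence[Ray], tol: float | None = None, *, default_tol: float = 0.1
) -> TriangulationResult:
    """Triangulate a fly position from 2-3 rays of distinct views.

    The triangulation is successful when the *minimum* pairwise
    closest-approach distance is within ``tol`` (two out of three rays
    crossing suffice).  The returned point is the midpoint of the closest
    pair; when all three pairs cross within tolerance, the centroid of the
    three pair midpoints is returned instead.
    """
    if tol is None:
        tol = default_tol
    if tol <= 0:
        raise GeometryError("tolerance must be positive")
    rays = list(rays)
    if len(rays) < 2:
        raise GeometryError("triangulation needs at least two rays")
    views = [r.view for r in rays]
    if len(set(views)) != len(views):
        raise GeometryError("rays must come from distinct views")

    pairs = []
    for i in range(len(rays)):
        for j in range(i + 1, len(rays)):
            dist, mid = ray_pair_closest(rays[i], rays[j])
            pairs.append((dist, mid))
    dists = [d for d, _ in pairs]
    best = int(np.argmin(dists))
    min_dist = dists[best]
    success = min_dist <= tol
    if len(pairs) == 3 and all(d <= tol for d in dists):
        point = np.mean([m for _, m in pairs], axis=0)
    else:
        point = pairs[best][1]
    return TriangulationResult(success=success, point=point, min_pair_distance=min_dist)


def default_arena(
    *,
    camera_distance_mm: float = 95.0,
    hfov_deg: float = 50.0,
    width: int = 640,
    height: int = 480,
    mirror_angle_deg: float = 39.0,
    apex_offset_mm: float = 25.0,
    tube_radius_mm: float = 10.0,
    tube_height_mm: float = 50.0,
    tolerance_mm: float = 0.1,
) -> ArenaGeometry:
    """Build the default apparatus geometry.

    The camera sits on the -y axis at ``camera_distance_mm`` from the tube
    axis, at tube mid-height, looking along +y.  The two mirror planes
    contain vertical lines, meet at a vertical edge ``apex_offset_mm``
    behind the tube axis and each makes ``mirror_angle_deg`` with the
    chamber back wall (the x-z plane), opening toward the camera.
    """
    cam = CameraModel(
        center=(0.0, -camera_distance_mm, tube_height_mm / 2.0),
        optical_axis=(0.0, 1.0, 0.0),
        up=(0.0, 0.0, 1.0),
        hfov=hfov_deg,
        width=width,
        height=height,
    )
    a = math.radians(mirror_angle_deg)
    apex = np.array([0.0, apex_offset_mm, 0.0])
    # In-plane horizontal directions make the mirror angle with the x axis;
    # normals face the camera side (-y component).
    left = MirrorPlane(
        point=apex, normal=(math.sin(a), -math.cos(a), 0.0), label=View.LEFT
    )
    right = MirrorPlane(
        point=apex, normal=(-math.sin(a), -math.cos(a), 0.0), label=View.RIGHT
    )
    return ArenaGeometry(
        tube_radius=tube_radius_mm,
        tube_height=tube_height_mm,
        camera=cam,
        mirrors=(left, right),
        crossing_tolerance=tolerance_mm,
    )


def _tube_surface_samples(geom: ArenaGeometry, n_az: int = 48, n_z: int = 9) -> np.ndarray:
    az = np.linspace(0.0, 2.0 * math.pi, n_az, endpoint=False)
    zs = np.linspace(0.0, geom.tube_height, n_z)
    pts = [
        (geom.tube_radius * math.cos(a), geom.tube_radius * math.sin(a), z)
        for a in az
        for z in zs
    ]
    return np.array(pts)


def view_strip_boundaries(geom: ArenaGeometry) -> tuple[float, float]:
    """Pixel-column boundaries (b_left, b_right) separating the three views.

    Columns u < b_left belong to LEFT, b_left <= u <= b_right to DIRECT and
    u > b_right to RIGHT.  The boundaries are the midpoints between the
    projected pixel extents of the tube in adjacent views; an overlap of the
    extents raises :class:`GeometryError`.
    """
    extents = {}
    for view in (View.LEFT, View.DIRECT, View.RIGHT):
        us = [project_to_view(p, view, geom)[0] for p in _tube_surface_samples(geom)]
        extents[view] = (min(us), max(us))
    if not (
        extents[View.LEFT][1] < extents[View.DIRECT][0]
        and extents[View.DIRECT][1] < extents[View.RIGHT][0]
    ):
        raise GeometryError(
            "tube images of the three views overlap in pixel space; "
            "adjust mirror placement or tube size"
        )
    b_left = 0.5 * (extents[View.LEFT][1] + extents[View.DIRECT][0])
    b_right = 0.5 * (extents[View.DIRECT][1] + extents[View.RIGHT][0])
    return (b_left, b_right)


def assign_view(u: float, boundaries: tuple[float, float]) -> View:
    """Assign a pixel column to a view by the static strip partition."""
    b_left, b_right = boundaries
    if u < b_left:
        return View.LEFT
    if u > b_right:
        return View.RIGHT
    return View.DIRECT
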