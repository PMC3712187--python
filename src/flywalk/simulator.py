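"""Synthetic arena: ground-truth fly locomotion, detections and frames.

Flies walk on the inner glass surface of a vertical tube, so their state is
two-dimensional — azimuth and height on the cylinder — even though the
recorded positions are 3D.  Locomotion is a correlated random walk: each
frame the fly takes a step of length speed*dt along its current surface
heading, the heading diffuses with Gaussian angular noise, and for 15 s
after each tap the heading is pulled toward vertical (negative geotaxis:
flies climb after being knocked down).  Per-step speed is drawn from a
normal distribution around the phenotype's age-dependent mean and clipped
to the observed 0-20 mm/s range.

Phenotypes model progressive neurodegeneration as a linear decline of mean
speed after an onset age: mu(age) = mu0 * max(0, 1 - r * max(0, age - a0)).
The defaults give a healthy control with a broad speed distribution with
median ~10 mm/s, an innocuous Abeta40-like genotype, a slowly declining
Abeta42-like genotype and an aggressive Abeta42-arctic-like genotype that
is grossly impaired by day 7-10.

Falls are Poisson events during which the fly drops at 80 mm/s until it
reaches the floor; their frame-to-frame displacement far exceeds the 2 mm
walking gate, which is how the tracker excludes them.  Rendering projects
each fly into the direct and both mirror views, either directly to a
detections table (with optional pixel noise and per-view miss probability)
or to full grayscale frames with dark Gaussian fly blobs and a whole-frame
shake at each tap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import Frame
from .geometry import ArenaGeometry, View, default_arena, project_to_view
from .tracking import Candidate3D

__all__ = [
    "PhenotypeModel",
    "SimConfig",
    "FlyTruth",
    "CohortTruth",
    "PHENOTYPES",
    "simulate_trajectory",
    "simulate_cohort",
    "truth_candidates",
    "render_detections",
    "render_frames",
]

FALL_SPEED = 80.0  # mm/s; >> 2 mm per frame at 7-10 fps
FLIGHT_SPEED = 60.0  # mm/s surface dash standing in for flight bursts
SPEED_CLIP = (0.0, 20.0)  # mm/s, the observed walking range


@dataclass(frozen=True)
class PhenotypeModel:
    """Genotype phenotype: baseline speed and progressive decline.

    ``decline`` is the fractional speed loss per day after ``onset_day``;
    mean speed at a given age is
    ``mu0 * max(0, 1 - decline * max(0, age - onset_day))``.
    """

    label: str
    mu0: float = 10.0  # mm/s baseline mean walking speed
    decline: float = 0.0  # fraction/day
    onset_day: float = 0.0
    fall_rate: float = 0.5  # events/min per fly
    flight_rate: float = 0.0  # events/min per fly

    def __post_init__(self):
        if self.mu0 <= 0:
            raise ValueError("mu0 must be positive")
        if self.decline < 0:
            raise ValueError("decline must be >= 0")

    def mean_speed(self, age_days: float) -> float:
        return self.mu0 * max(0.0, 1.0 - self.decline * max(0.0, age_days - self.onset_day))


PHENOTYPES = {
    "control": PhenotypeModel(label="control"),
    "abeta40": PhenotypeModel(label="abeta40"),
    "abeta42": PhenotypeModel(label="abeta42", decline=0.05, onset_day=2.0),
    "abeta42_arctic": PhenotypeModel(label="abeta42_arctic", decline=0.12, onset_day=2.0),
}


@dataclass(frozen=True)
class SimConfig:
    """Session-level simulation parameters."""

    geometry: ArenaGeometry = field(default_factory=default_arena)
    fps: float = 10.0
    n_flies: int = 10
    duration: float = 90.0
    tap_times: tuple[float, ...] = (0.0, 30.0, 60.0)
    tap_shake: float = 0.5  # s of whole-frame disturbance per tap
    geotaxis_duration: float = 15.0  # s of upward bias after each tap
    speed_cv: float = 0.3  # per-step speed sd as a fraction of the mean
    turn_sigma: float = 0.4  # rad/step heading diffusion
    geotaxis_pull: float = 0.3  # per-step fractional pull of heading to vertical
    seed: int = 0

    def __post_init__(self):
        if not 1.0 <= self.fps <= 100.0:
            raise ValueError("fps out of range")
        if self.n_flies < 1:
            raise ValueError("n_flies must be >= 1")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    @property
    def window_starts(self) -> tuple[float, ...]:
        """Ground-truth analysis-window starts: taps end after the shake."""
        return tuple(t + self.tap_shake for t in self.tap_times)


@dataclass
class FlyTruth:
    """Ground truth for one fly: positions and motion state per frame."""

    fly_id: int
    times: np.ndarray
    positions: np.ndarray  # (n, 3) mm
    states: np.ndarray  # 'walk' | 'fall' | 'flight'

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fly_id": self.fly_id,
                "time_s": self.times,
                "x_mm": self.positions[:, 0],
                "y_mm": self.positions[:, 1],
                "z_mm": self.positions[:, 2],
                "state": self.states,
            }
        )


@dataclass
class CohortTruth:
    """Ground truth of one session: all flies plus the tap schedule."""

    flies: list[FlyTruth]
    config: SimConfig
    model: PhenotypeModel
    age_days: float

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([f.to_frame() for f in self.flies], ignore_index=True)


def _wrap_angle(a: float) -> float:
    return (a + math.pi) % (2.0 * math.pi) - math.pi


def simulate_trajectory(
    model: PhenotypeModel,
    age_days: float,
    cfg: SimConfig,
    rng: np.random.Generator,
    fly_id: int = 0,
) -> FlyTruth:
    """Simulate one fly over the full session.

    The fly walks on the cylinder surface with heading persistence and
    post-tap upward bias; Poisson fall (and optionally flight) events
    interrupt walking with fast displacements.  Samples are labelled
    'fall'/'flight' only while the motion on *both* sides of the sample is
    faster than the walking gate, so gated linking provably isolates them.
    """
    geom = cfg.geometry
    dt = 1.0 / cfg.fps
    mu = model.mean_speed(age_days)
    n = cfg.n_frames
    r = geom.tube_radius
    H = geom.tube_height

    az = rng.uniform(0.0, 2.0 * math.pi)
    z = rng.uniform(0.0, 0.4 * H)
    heading = rng.uniform(-math.pi, math.pi)  # 0 = straight up

    def next_event(rate_per_min):
        if rate_per_min <= 0:
            return math.inf
        return rng.exponential(60.0 / rate_per_min)

    t_fall = next_event(model.fall_rate)
    t_flight = next_event(model.flight_rate)
    falling = False
    flight_left = 0.0

    times = cfg.frame_times
    positions = np.empty((n, 3))
    states = np.empty(n, dtype=object)

    for i in range(n):
        t = times[i]
        positions[i] = (r * math.cos(az), r * math.sin(az), z)
        # 'fall'/'flight' labels require fast motion both into and out of
        # the sample, so gated linking provably leaves them unlinked.
        if falling and z > 2.5:
            states[i] = "fall"
        elif flight_left > dt:
            states[i] = "flight"
        else:
            states[i] = "walk"

        # --- advance to the next frame ---
        if not falling and t >= t_fall and z > 5.0:
            falling = True
            t_fall = t + next_event(model.fall_rate)
        if falling:
            z = z - FALL_SPEED * dt
            if z <= 0.0:
                z = 0.0
                falling = False
            continue
        if flight_left <= 0.0 and t >= t_flight:
            flight_left = 0.5
            t_flight = t + next_event(model.flight_rate)
        if flight_left > 0.0:
            speed = FLIGHT_SPEED
            flight_left -= dt
        else:
            speed = float(np.clip(rng.normal(mu, cfg.speed_cv * mu), *SPEED_CLIP)) if mu > 0 else 0.0
        heading = _wrap_angle(heading + rng.normal(0.0, cfg.turn_sigma))
        in_geotaxis = any(
            tap + cfg.tap_shake <= t < tap + cfg.tap_shake + cfg.geotaxis_duration
            for tap in cfg.tap_times
        )
        if in_geotaxis:
            heading = _wrap_angle((1.0 - cfg.geotaxis_pull) * heading)
        arc = speed * dt
        dz = arc * math.cos(heading)
        daz = arc * math.sin(heading) / r
        z_new = z + dz
        if z_new < 0.0 or z_new > H:
            heading = _wrap_angle(math.pi - heading)  # reflect the vertical component
            dz = -dz
            z_new = min(max(z + dz, 0.0), H)
        z = z_new
        az = (az + daz) % (2.0 * math.pi)

    return FlyTruth(fly_id=fly_id, times=times.copy(), positions=positions, states=states)


def simulate_cohort(
    model: PhenotypeModel,
    age_days: float,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> CohortTruth:
    """Simulate all flies of one tube over one session.

    Deterministic for a fixed ``cfg.seed`` (or a caller-provided rng).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    flies = [
        simulate_trajectory(model, age_days, cfg, rng, fly_id=i)
        for i in range(cfg.n_flies)
    ]
    return CohortTruth(flies=flies, config=cfg, model=model, age_days=age_days)


def truth_candidates(truth: CohortTruth) -> list[list[Candidate3D]]:
    """Ground-truth positions packaged as per-frame linker candidates.

    Bypasses rendering/detection/triangulation: useful for testing the
    linker and the statistics on noiseless input.
    """
    n = truth.config.n_frames
    frames: list[list[Candidate3D]] = [[] for _ in range(n)]
    for fly in truth.flies:
        for i in range(len(fly.times)):
            frames[i].append(
                Candidate3D(
                    frame_index=i,
                    time=float(fly.times[i]),
                    position=fly.positions[i],
                    n_views=3,
                    min_pair_distance=0.0,
                )
            )
    return frames


def render_detections(
    truth: CohortTruth,
    geom: ArenaGeometry | None = None,
    *,
    noise_px: float = 0.0,
    miss_prob: float | dict[View, float] = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Project ground truth into the three views as a detections table.

    Adds isotropic Gaussian pixel noise of sd ``noise_px``; detections
    falling outside the sensor are dropped; ``miss_prob`` (scalar or
    per-view) randomly removes detections.
    """
    if geom is None:
        geom = truth.config.geometry
    if rng is None:
        rng = np.random.default_rng(truth.config.seed + 1)
    if not isinstance(miss_prob, dict):
        miss_prob = {v: float(miss_prob) for v in View}
    cam = geom.camera
    rows = []
    for fly in truth.flies:
        for i in range(len(fly.times)):
            p = fly.positions[i]
            for view in (View.DIRECT, View.LEFT, View.RIGHT):
                u, v = project_to_view(p, view, geom)
                if noise_px > 0:
                    u += rng.normal(0.0, noise_px)
                    v += rng.normal(0.0, noise_px)
                if not (-0.5 <= u <= cam.width - 0.5 and -0.5 <= v <= cam.height - 0.5):
                    continue
                if miss_prob.get(view, 0.0) > 0 and rng.random() < miss_prob[view]:
                    continue
                rows.append(
                    {
                        "frame": i,
                        "time_s": fly.times[i],
                        "view": view.value,
                        "u_px": u,
                        "v_px": v,
                        "area_px2": 12,
                        "bbox_x": int(u) - 2,
                        "bbox_y": int(v) - 2,
                        "bbox_w": 5,
                        "bbox_h": 5,
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "frame", "time_s", "view", "u_px", "v_px", "area_px2",
            "bbox_x", "bbox_y", "bbox_w", "bbox_h",
        ],
    )
    return df.sort_values(["frame", "view", "u_px"], kind="stable").reset_index(drop=True)


def _stamp_blob(img: np.ndarray, u: float, v: float, sigma: float, amp: float):
    h, w = img.shape
    rad = int(math.ceil(4 * sigma))
    x0, x1 = max(0, int(u) - rad), min(w, int(u) + rad + 1)
    y0, y1 = max(0, int(v) - rad), min(h, int(v) + rad + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - u
    ys = np.arange(y0, y1) - v
    g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * sigma * sigma))
    img[y0:y1, x0:x1] -= amp * g


def render_frames(
    truth: CohortTruth,
    geom: ArenaGeometry | None = None,
    *,
    blob_sigma: float = 1.5,
    blob_amplitude: float = 120.0,
    background_level: float = 200.0,
    noise_sigma: float = 2.0,
    rng: np.random.Generator | None = None,
) -> list[Frame]:
    """Render the session as grayscale frames.

    Light uniform background, dark Gaussian blobs at each projected fly
    position, Gaussian sensor noise, and a whole-frame shake (translation
    of the scene) for ``tap_shake`` seconds at each tap time.
    """
    if geom is None:
        geom = truth.config.geometry
    if rng is None:
        rng = np.random.default_rng(truth.config.seed + 2)
    cfg = truth.config
    cam = geom.camera
    h, w = cam.height, cam.width
    # static background texture so a shake produces large frame differences
    yy, xx = np.mgrid[0:h, 0:w]
    base = (
        background_level
        - 20.0 * np.sin(2.0 * math.pi * xx / 64.0)
        - 20.0 * np.cos(2.0 * math.pi * yy / 64.0)
    ).astype(np.float32)

    frames = []
    times = cfg.frame_times
    for i, t in enumerate(times):
        shaking = any(tap <= t < tap + cfg.tap_shake for tap in cfg.tap_times)
        if shaking:
            dx, dy = rng.integers(-8, 9, size=2)
            img = np.roll(np.roll(base, int(dy), axis=0), int(dx), axis=1).copy()
        else:
            img = base.copy()
        for fly in truth.flies:
            p = fly.positions[i]
            for view in (View.DIRECT, View.LEFT, View.RIGHT):
                u, v = project_to_view(p, view, geom)
                if -0.5 <= u <= w - 0.5 and -0.5 <= v <= h - 0.5:
                    _stamp_blob(img, u, v, blob_sigma, blob_amplitude)
        # a tap saturates the motion energy: besides the translation, the
        # sensor noise is boosted while the tube is being dropped back in
        eff_noise = noise_sigma + (25.0 if shaking else 0.0)
        if eff_noise > 0:
            img += rng.normal(0.0, eff_noise, size=img.shape).astype(np.float32)
        np.clip(img, 0.0, 255.0, out=img)
        frames.append(Frame(index=i, time=float(t), pixels=img.astype(np.uint8)))
    return frames
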