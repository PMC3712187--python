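"""Blob detection: locate flies in each view of each frame.

Flies appear as small dark blobs on a light background (the chamber is lit
through a frosted lid or by internal LEDs).  Detection is
background-subtraction based: a temporal median background is estimated
from a sample of frames, each frame is compared against it by absolute
difference (so polarity does not matter), and connected components above a
threshold are emitted as detections with intensity-weighted sub-pixel
centroids.  Each detection is assigned to the DIRECT/LEFT/RIGHT view by the
static pixel-strip partition derived from the arena geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .geometry import ArenaGeometry, View, assign_view, view_strip_boundaries

__all__ = ["Frame", "Detection", "estimate_background", "detect_blobs"]


@dataclass(frozen=True)
class Frame:
    """One grayscale video frame."""

    index: int
    time: float
    pixels: np.ndarray  # (height, width)

    def __post_init__(self):
        if np.asarray(self.pixels).ndim != 2:
            raise ValueError("frame pixels must be a 2D array")


@dataclass(frozen=True)
class Detection:
    """One fly blob in one view of one frame.

    ``centroid`` is the intensity-weighted sub-pixel (u, v) position;
    ``bbox`` is the integer (x, y, w, h) pixel rectangle of the component.
    """

    frame_index: int
    time: float
    view: View
    centroid: tuple[float, float]
    area: int
    bbox: tuple[int, int, int, int]


def estimate_background(frames: Sequence[Frame], sample_step: int = 1) -> np.ndarray:
    """Per-pixel temporal median over a sample of the frames.

    The median rejects moving flies as long as each pixel is fly-free in
    more than half of the sampled frames.
    """
    sampled = list(frames)[::max(1, int(sample_step))]
    if len(sampled) < 5:
        raise ValueError("background estimation needs at least 5 sampled frames")
    stack = np.stack([np.asarray(f.pixels, dtype=np.float32) for f in sampled])
    return np.median(stack, axis=0)


def detect_blobs(
    frame: Frame,
    background: np.ndarray,
    geom: ArenaGeometry | None = None,
    *,
    min_area: int = 4,
    threshold: float | None = None,
    strip_boundaries: tuple[float, float] | None = None,
) -> list[Detection]:
    """Detect fly blobs in one frame against a background image.

    Parameters
    ----------
    threshold : float, optional
        Absolute-difference threshold.  Defaults to 25% of the frame's
        intensity range.
    min_area : int
        Minimum connected-component area in pixels squared.
    geom, strip_boundaries
        Either the arena geometry (from which the view strips are derived)
        or precomputed strip boundaries.  With neither, all detections are
        labelled DIRECT.
    """
    pixels = np.asarray(frame.pixels, dtype=np.float32)
    background = np.asarray(background, dtype=np.float32)
    if pixels.shape != background.shape:
        raise ValueError(
            f"frame shape {pixels.shape} != background shape {background.shape}"
        )
    if threshold is None:
        rng = float(pixels.max() - pixels.min())
        threshold = 0.25 * rng
    if threshold <= 0:
        return []
    if strip_boundaries is None and geom is not None:
        strip_boundaries = view_strip_boundaries(geom)

    diff = np.abs(pixels - background)
    mask = diff > threshold
    labels, n = ndimage.label(mask)
    if n == 0:
        return []
    detections: list[Detection] = []
    slices = ndimage.find_objects(labels)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    # intensity-weighted centroids in (row, col) order
    centroids = ndimage.center_of_mass(diff, labels, index=np.arange(1, n + 1))
    for k in range(n):
        area = int(areas[k])
        if area < min_area:
            continue
        cy, cx = centroids[k]
        sy, sx = slices[k]
        bbox = (int(sx.start), int(sy.start), int(sx.stop - sx.start), int(sy.stop - sy.start))
        view = (
            assign_view(float(cx), strip_boundaries)
            if strip_boundaries is not None
            else View.DIRECT
        )
        detections.append(
            Detection(
                frame_index=frame.index,
                time=frame.time,
                view=view,
                centroid=(float(cx), float(cy)),
                area=area,
                bbox=bbox,
            )
        )
    return detections
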