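"""Foreground segmentation, blob extraction, and orientation.

A fly pixel must satisfy two conditions against the modeled background:
its own intensity is below ``fg_max_value`` (flies are dark) and the
background exceeds it by more than ``bg_min_diff`` (which rejects dark
impurities that are part of the static scene). Surviving pixels are
grouped into 8-connected components; components smaller than
``min_area`` are treated as noise. The body position is the centroid
(barycenter) of the component, the body axis is the long side of its
minimum-area enclosing rectangle, and head/tail polarity is resolved by
the direction of motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "Blob",
    "segment_foreground",
    "find_blobs",
    "body_axis",
    "min_area_rect_angle",
    "resolve_heading",
]

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass
class Blob:
    """A connected foreground component."""

    area: int
    centroid: tuple[float, float]  # (x, y), fractional pixels
    bbox: tuple[int, int, int, int]  # (x0, y0, x1, y1), half-open
    pixels: np.ndarray  # (n, 2) array of (x, y) integer coordinates

    _axis_angle: float | None = None

    @property
    def axis_angle(self) -> float:
        """Body-axis angle in [0, 180), computed on first access."""
        if self._axis_angle is None:
            self._axis_angle = body_axis(self)
        return self._axis_angle


def segment_foreground(
    frame: np.ndarray,
    background: np.ndarray,
    fg_max_value: int = 120,
    bg_min_diff: int = 70,
) -> np.ndarray:
    """Binary fly mask: ``frame < fg_max_value`` and ``background - frame > bg_min_diff``.

    The difference is signed (background minus frame): the scene is
    bright and flies are dark, so pixels brighter than the background
    are never foreground.
    """
    frame = np.asarray(frame)
    background = np.asarray(background)
    if frame.shape != background.shape:
        raise ValueError(f"frame shape {frame.shape} != background shape {background.shape}")
    diff = background.astype(np.int16) - frame.astype(np.int16)
    return (frame < fg_max_value) & (diff > bg_min_diff)


def find_blobs(mask: np.ndarray, min_area: int = 4) -> list[Blob]:
    """8-connected components of the mask with area >= min_area.

    Centroids are the unweighted mean of member pixel coordinates,
    returned as fractional (x, y).
    """
    labels, n = ndimage.label(mask, structure=_EIGHT_CONN)
    if n == 0:
        return []
    blobs: list[Blob] = []
    objects = ndimage.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sub = labels[sl] == lab
        area = int(sub.sum())
        if area < min_area:
            continue
        ys, xs = np.nonzero(sub)
        y0, x0 = sl[0].start, sl[1].start
        xs = xs + x0
        ys = ys + y0
        centroid = (float(xs.mean()), float(ys.mean()))
        bbox = (int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
        blobs.append(Blob(area=area, centroid=centroid, bbox=bbox, pixels=np.column_stack([xs, ys])))
    return blobs


def _convex_hull(points: np.ndarray) -> np.ndarray:
    """Monotone-chain convex hull; returns hull vertices counterclockwise.

    Collinear inputs return the two extreme points.
    """
    pts = np.unique(points, axis=0)
    if len(pts) <= 2:
        return pts.astype(float)
    # lexicographic sort by (x, y)
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order].astype(float)

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list[np.ndarray] = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list[np.ndarray] = []
    for p in pts[::-1]:
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = np.array(lower[:-1] + upper[:-1])
    if len(hull) < 3:  # all points collinear
        return np.array([pts[0], pts[-1]])
    return hull


def min_area_rect_angle(points: np.ndarray) -> float:
    """Angle in [0, 180) of the longer side of the minimum-area rectangle.

    Rotating calipers over the convex hull: the minimum-area enclosing
    rectangle has a side collinear with a hull edge. Ties (equal areas,
    or a square where both sides have equal length) resolve to the
    first hull edge encountered, which makes the result deterministic.
    Degenerate inputs (collinear points) return the angle of the extent
    direction; a single point returns 0.
    """
    pts = np.asarray(points, dtype=float)
    hull = _convex_hull(pts)
    if len(hull) == 1:
        return 0.0
    if len(hull) == 2:
        d = hull[1] - hull[0]
        return float(np.degrees(np.arctan2(d[1], d[0])) % 180.0)
    best_area = np.inf
    best_angle = 0.0
    n = len(hull)
    for i in range(n):
        edge = hull[(i + 1) % n] - hull[i]
        norm = np.hypot(edge[0], edge[1])
        if norm == 0:
            continue
        ux, uy = edge / norm
        # rotate all hull points into the edge frame
        xs = hull[:, 0] * ux + hull[:, 1] * uy
        ys = -hull[:, 0] * uy + hull[:, 1] * ux
        w = xs.max() - xs.min()
        h = ys.max() - ys.min()
        area = w * h
        if area < best_area - 1e-12:
            best_area = area
            edge_angle = np.degrees(np.arctan2(uy, ux))
            # long side: along the edge if w >= h, else perpendicular
            best_angle = edge_angle if w >= h else edge_angle + 90.0
    return float(best_angle % 180.0)


def body_axis(blob: Blob) -> float:
    """Body-axis angle of a blob in degrees, in [0, 180)."""
    return min_area_rect_angle(blob.pixels)


def _circ_diff(a: float, b: float) -> float:
    """Smallest absolute difference between two angles in degrees."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def resolve_heading(
    axis_angle: float,
    velocity: tuple[float, float],
    prev_heading: float | None,
    speed_min: float = 1.0,
) -> float | None:
    """Pick head vs tail along the body axis using the motion direction.

    Of the two candidates ``axis`` and ``axis + 180``, return the one
    within 90 degrees of the velocity direction when speed is at least
    ``speed_min`` px/frame; otherwise carry the previous heading (or
    return None if there is none yet).
    """
    vx, vy = velocity
    speed = float(np.hypot(vx, vy))
    if speed < speed_min:
        return prev_heading
    vel_angle = float(np.degrees(np.arctan2(vy, vx)) % 360.0)
    c1 = axis_angle % 360.0
    c2 = (axis_angle + 180.0) % 360.0
    return c1 if _circ_diff(c1, vel_angle) <= _circ_diff(c2, vel_angle) else c2
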