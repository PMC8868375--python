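"""Arena layout, per-arena blob assignment, and trajectory assembly.

Each circular arena houses exactly one fly, so arenas are hard
partitions of the image: a blob belongs to the arena whose circle
contains its centroid, and at most one blob (the largest) is kept per
arena per frame. Frames where an arena has no accepted blob are flagged
invalid and the last valid position is carried forward, which biases
gaps toward "inactive" — consistent with the sleep definition, since a
dark fly vanishing on a bright field nearly always means stillness or
occlusion by the rim rather than motion.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config_io import FrameStream, RunConfig, analysis_window
from .detect import Blob, find_blobs, resolve_heading, segment_foreground

__all__ = [
    "ArenaLayout",
    "TrajectorySet",
    "build_layout",
    "assign_blobs",
    "track",
    "save_trajectories",
    "load_trajectories",
]


@dataclass
class ArenaLayout:
    """Indexed circles (cx, cy, r) partitioning the image, row-major."""

    centers: np.ndarray  # (n, 2) of (cx, cy)
    radii: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        self.radii = np.broadcast_to(
            np.asarray(self.radii, dtype=float), (len(self.centers),)
        ).copy()

    def __len__(self) -> int:
        return len(self.centers)

    def validate(self, height: int | None = None, width: int | None = None) -> None:
        n = len(self)
        if n == 0:
            raise ValueError("arena layout is empty")
        for i in range(n):
            for j in range(i + 1, n):
                d = np.hypot(*(self.centers[i] - self.centers[j]))
                if d < self.radii[i] + self.radii[j]:
                    raise ValueError(f"arenas {i} and {j} overlap")
        if height is not None and width is not None:
            for i, ((cx, cy), r) in enumerate(zip(self.centers, self.radii)):
                if cx - r < 0 or cy - r < 0 or cx + r > width or cy + r > height:
                    raise ValueError(f"arena {i} extends outside the frame")

    def contains(self, arena: int, x: float, y: float) -> bool:
        cx, cy = self.centers[arena]
        return np.hypot(x - cx, y - cy) <= self.radii[arena]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "arena": np.arange(len(self)),
                "cx": self.centers[:, 0],
                "cy": self.centers[:, 1],
                "r": self.radii,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ArenaLayout":
        df = df.sort_values("arena")
        return cls(df[["cx", "cy"]].to_numpy(), df["r"].to_numpy())

    @classmethod
    def grid(
        cls,
        rows: int,
        cols: int,
        radius: float,
        spacing: float,
        origin: tuple[float, float] | None = None,
    ) -> "ArenaLayout":
        """Regular rows x cols grid of equal circles, row-major order."""
        if origin is None:
            origin = (spacing / 2.0, spacing / 2.0)
        xs = origin[0] + spacing * np.arange(cols)
        ys = origin[1] + spacing * np.arange(rows)
        centers = [(x, y) for y in ys for x in xs]
        return cls(np.array(centers), np.full(rows * cols, float(radius)))


@dataclass
class TrajectorySet:
    """Per-arena, per-frame tracking product.

    ``x``/``y``/``heading`` are (arenas, frames) float arrays; heading
    is NaN where undefined. ``valid`` marks frames with an actual
    detection; invalid frames carry the most recent valid position
    (leading gaps are backfilled from the first valid detection).
    ``frame_offset`` is the absolute index of the first tracked frame
    in the source video.
    """

    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    valid: np.ndarray
    fps: float
    frame_offset: int = 0
    layout: ArenaLayout | None = field(default=None, repr=False)

    @property
    def n_arenas(self) -> int:
        return self.x.shape[0]

    @property
    def frame_count(self) -> int:
        return self.x.shape[1]

    def positions(self, arena: int) -> np.ndarray:
        """(frames, 2) carried positions of one arena."""
        return np.column_stack([self.x[arena], self.y[arena]])

    def to_frame(self) -> pd.DataFrame:
        n_a, n_f = self.x.shape
        return pd.DataFrame(
            {
                "arena": np.repeat(np.arange(n_a), n_f),
                "frame": np.tile(np.arange(n_f) + self.frame_offset, n_a),
                "x": self.x.ravel(),
                "y": self.y.ravel(),
                "heading_deg": self.heading.ravel(),
                "valid": self.valid.ravel().astype(int),
            }
        )


def build_layout(config: RunConfig, background: np.ndarray | None = None) -> ArenaLayout:
    """Resolve the arena layout from config (manual) or the background (auto)."""
    ac = config.arena
    h, w = (background.shape if background is not None else (None, None))
    if ac.mode == "manual":
        if ac.centers is not None:
            if ac.radius is None:
                raise ValueError("manual layout with centers requires 'radius'")
            layout = ArenaLayout(np.asarray(ac.centers, dtype=float), np.full(len(ac.centers), ac.radius))
        elif ac.rows and ac.cols:
            if ac.radius is None:
                raise ValueError("grid layout requires 'radius'")
            spacing = ac.spacing if ac.spacing is not None else 2.0 * ac.radius + 4.0
            layout = ArenaLayout.grid(ac.rows, ac.cols, ac.radius, spacing, ac.origin)
        else:
            raise ValueError("manual arena layout requires 'centers' or 'rows'+'cols'")
    elif ac.mode == "auto":
        if background is None:
            raise ValueError("auto arena layout requires a background image")
        layout = detect_circles(background, ac.radius)
    else:  # pragma: no cover - guarded by ArenaConfig
        raise ValueError(f"unknown arena mode {ac.mode!r}")
    layout.validate(h, w)
    return layout


def detect_circles(background: np.ndarray, radius_hint: float | None = None) -> ArenaLayout:
    """Detect dark circular arena rims on the background via a Hough transform."""
    from skimage.feature import canny
    from skimage.transform import hough_circle, hough_circle_peaks

    img = background.astype(float) / 255.0
    edges = canny(img, sigma=1.5)
    if radius_hint is not None:
        radii = np.arange(max(3, int(radius_hint * 0.8)), int(radius_hint * 1.2) + 1)
    else:
        radii = np.arange(6, min(background.shape) // 2)
    h = hough_circle(edges, radii)
    _, cxs, cys, rs = hough_circle_peaks(
        h, radii, min_xdistance=int(radii.min()), min_ydistance=int(radii.min()),
        threshold=0.5 * h.max(),
    )
    if len(cxs) == 0:
        raise ValueError("auto arena detection found no circles")
    centers = np.column_stack([cxs, cys]).astype(float)
    rs = rs.astype(float)
    # row-major ordering: cluster rows by vertical proximity, then sort by x
    order = np.argsort(centers[:, 1])
    rows: list[list[int]] = []
    for i in order:
        if rows and abs(centers[i, 1] - centers[rows[-1][0], 1]) <= rs.mean():
            rows[-1].append(i)
        else:
            rows.append([i])
    idx = [i for row in rows for i in sorted(row, key=lambda j: centers[j, 0])]
    return ArenaLayout(centers[idx], rs[idx])


def assign_blobs(blobs: list[Blob], layout: ArenaLayout) -> list[Blob | None]:
    """One blob per arena: the largest whose centroid falls in the circle.

    Ties on area break toward the topmost, then leftmost centroid.
    Blobs outside every circle are dropped; arenas may come back empty.
    """
    chosen: list[Blob | None] = [None] * len(layout)
    for blob in blobs:
        bx, by = blob.centroid
        for a in range(len(layout)):
            if layout.contains(a, bx, by):
                cur = chosen[a]
                if cur is None or (blob.area, -by, -bx) > (cur.area, -cur.centroid[1], -cur.centroid[0]):
                    chosen[a] = blob
                break  # circles are disjoint
    return chosen


def track(
    stream: FrameStream,
    background: np.ndarray,
    layout: ArenaLayout,
    config: RunConfig,
) -> TrajectorySet:
    """Run the full per-frame pipeline over the analysis window.

    For each frame: segment against the background, extract blobs,
    assign one per arena, update positions and resolve headings from
    the motion direction. Missing detections freeze the position
    (``valid=False``).
    """
    if len(layout) == 0:
        raise ValueError("empty arena layout")
    start, end = analysis_window(config, stream)
    n_frames = end - start
    n_arenas = len(layout)
    x = np.full((n_arenas, n_frames), np.nan)
    y = np.full((n_arenas, n_frames), np.nan)
    heading = np.full((n_arenas, n_frames), np.nan)
    valid = np.zeros((n_arenas, n_frames), dtype=bool)

    prev_pos: list[tuple[float, float] | None] = [None] * n_arenas
    prev_heading: list[float | None] = [None] * n_arenas

    for f in range(n_frames):
        frame = stream.frame(start + f)
        mask = segment_foreground(frame, background, config.fg_max_value, config.bg_min_diff)
        blobs = find_blobs(mask, config.min_area)
        chosen = assign_blobs(blobs, layout)
        for a, blob in enumerate(chosen):
            if blob is None:
                if prev_pos[a] is not None:
                    x[a, f], y[a, f] = prev_pos[a]
                    hd = prev_heading[a]
                    heading[a, f] = np.nan if hd is None else hd
                continue
            cx, cy = blob.centroid
            if prev_pos[a] is None:
                vel = (0.0, 0.0)
            else:
                vel = (cx - prev_pos[a][0], cy - prev_pos[a][1])
            hd = resolve_heading(blob.axis_angle, vel, prev_heading[a], config.speed_min)
            x[a, f], y[a, f] = cx, cy
            heading[a, f] = np.nan if hd is None else hd
            valid[a, f] = True
            prev_pos[a] = (cx, cy)
            prev_heading[a] = hd

    # backfill leading gaps from the first valid detection
    for a in range(n_arenas):
        if not valid[a].any():
            # never detected: park at the arena center
            x[a, :], y[a, :] = layout.centers[a]
            continue
        first = int(np.argmax(valid[a]))
        x[a, :first] = x[a, first]
        y[a, :first] = y[a, first]

    return TrajectorySet(
        x=x, y=y, heading=heading, valid=valid,
        fps=stream.fps, frame_offset=start, layout=layout,
    )


def save_trajectories(traj: TrajectorySet, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Dump trajectories as an NPY array plus a portable CSV mirror.

    The array has shape (arenas, frames, 4) with planes x, y, heading
    (NaN = undefined) and valid (0/1).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arr = np.stack([traj.x, traj.y, traj.heading, traj.valid.astype(float)], axis=2)
    npy = out_dir / "trajectories.npy"
    np.save(npy, arr)
    csv = out_dir / "trajectories.csv"
    traj.to_frame().to_csv(csv, index=False, float_format="%.4f")
    return {"npy": npy, "csv": csv}


def load_trajectories(npy_path: str | os.PathLike, fps: float, frame_offset: int = 0) -> TrajectorySet:
    arr = np.load(npy_path)
    return TrajectorySet(
        x=arr[:, :, 0], y=arr[:, :, 1], heading=arr[:, :, 2],
        valid=arr[:, :, 3] > 0.5, fps=fps, frame_offset=frame_offset,
    )
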