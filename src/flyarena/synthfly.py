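"""Synthetic multi-arena fly videos with exact ground truth.

The generator emulates the scene the tracker is built for: a bright,
static background; a grid of circular arenas; one dark elliptical fly
per arena performing a bounded persistent random walk (heading
perturbed by Gaussian turns, step lengths truncated-Gaussian,
specular reflection off the arena wall); optional planted immobile
("sleep") intervals; mild iid Gaussian pixel noise; and optional static
dark impurity specks outside the arenas. Everything is a pure function
of the parameter set, so every downstream stage can be tested against
exact ground truth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .arenas import ArenaLayout
from .config_io import ArrayFrameStream, RunConfig, write_config

__all__ = [
    "SynthParams",
    "GroundTruth",
    "simulate_trajectory",
    "render_video",
    "render_static_scene",
    "simulate",
    "write_fixture",
]


@dataclass
class SynthParams:
    """Scene and motion parameters for one synthetic recording.

    Defaults render a fly that is unambiguously detectable by the
    default segmentation thresholds: intensity 40 on a 230 background
    satisfies both ``frame < 120`` and ``background - frame > 70``.
    """

    rows: int = 1
    cols: int = 1
    arena_radius: float = 20.0
    spacing: float | None = None  # center-to-center; default 2r + 8
    fly_semi_axes: tuple[float, float] = (3.0, 1.5)  # (major, minor) px
    fly_intensity: int = 40
    background_intensity: int = 230
    rim_intensity: int = 170
    draw_rims: bool = True
    noise_sd: float = 0.0
    impurity_count: int = 0
    impurity_intensity: int = 30
    speed_mean: float = 2.0  # px/frame
    speed_sd: float | None = None  # default speed_mean / 3
    turn_sd: float = 0.15  # radians/frame
    sleep_schedule: list[tuple[int, int, int]] = field(default_factory=list)
    duration: int = 300  # frames
    fps: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed_sd is None:
            self.speed_sd = self.speed_mean / 3.0
        a, b = self.fly_semi_axes
        if a < b:
            raise ValueError("fly_semi_axes must be (major, minor) with major >= minor")
        if 4.0 * a * b < 4.0:
            raise ValueError("fly body smaller than 4 px is treated as noise; enlarge fly_semi_axes")
        if not (0 <= self.fly_intensity <= 255 and 0 <= self.background_intensity <= 255):
            raise ValueError("intensities must be in [0, 255]")
        if self.fly_intensity >= 120 or self.background_intensity - self.fly_intensity <= 70:
            raise ValueError("fly would not satisfy the default segmentation thresholds")
        margin = max(a, b) + 1.0
        if self.arena_radius <= margin + 1.0:
            raise ValueError("arena_radius too small for the fly body")
        for arena, start, end in self.sleep_schedule:
            if not (0 <= start < end <= self.duration):
                raise ValueError(f"sleep interval ({arena}, {start}, {end}) outside [0, {self.duration})")
            if not (0 <= arena < self.rows * self.cols):
                raise ValueError(f"sleep interval references unknown arena {arena}")

    @property
    def n_arenas(self) -> int:
        return self.rows * self.cols

    def layout(self) -> ArenaLayout:
        spacing = self.spacing if self.spacing is not None else 2.0 * self.arena_radius + 8.0
        return ArenaLayout.grid(self.rows, self.cols, self.arena_radius, spacing)

    def frame_shape(self) -> tuple[int, int]:
        spacing = self.spacing if self.spacing is not None else 2.0 * self.arena_radius + 8.0
        return int(round(self.rows * spacing)), int(round(self.cols * spacing))


@dataclass
class GroundTruth:
    """Simulator-emitted true trajectories and sleep flags.

    Arrays are (arenas, frames); headings are degrees in [0, 360).
    """

    x: np.ndarray
    y: np.ndarray
    heading_deg: np.ndarray
    asleep: np.ndarray  # bool

    @property
    def n_arenas(self) -> int:
        return self.x.shape[0]

    @property
    def frame_count(self) -> int:
        return self.x.shape[1]

    def speed(self) -> np.ndarray:
        """True per-frame displacement magnitude, (arenas, frames); frame 0 is 0."""
        dx = np.diff(self.x, axis=1, prepend=self.x[:, :1])
        dy = np.diff(self.y, axis=1, prepend=self.y[:, :1])
        return np.hypot(dx, dy)

    def to_frame(self) -> pd.DataFrame:
        n_a, n_f = self.x.shape
        return pd.DataFrame(
            {
                "arena": np.repeat(np.arange(n_a), n_f),
                "frame": np.tile(np.arange(n_f), n_a),
                "x": self.x.ravel(),
                "y": self.y.ravel(),
                "heading_deg": self.heading_deg.ravel(),
                "asleep": self.asleep.ravel().astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GroundTruth":
        n_a = df["arena"].nunique()
        n_f = df["frame"].nunique()
        df = df.sort_values(["arena", "frame"])
        shape = (n_a, n_f)
        return cls(
            x=df["x"].to_numpy().reshape(shape),
            y=df["y"].to_numpy().reshape(shape),
            heading_deg=df["heading_deg"].to_numpy().reshape(shape),
            asleep=df["asleep"].to_numpy().reshape(shape).astype(bool),
        )


def _sleep_mask(params: SynthParams) -> np.ndarray:
    asleep = np.zeros((params.n_arenas, params.duration), dtype=bool)
    for arena, start, end in params.sleep_schedule:
        asleep[arena, start:end] = True
    return asleep


def simulate_trajectory(params: SynthParams) -> GroundTruth:
    """Bounded persistent random walk per arena with planted sleep.

    Each awake frame perturbs the heading by ``N(0, turn_sd)`` and
    advances by a step of length ``max(0, N(speed_mean, speed_sd))``;
    the wall reflects the heading specularly. During scheduled sleep
    the position is frozen and the heading held. Deterministic given
    the seed.
    """
    rng = np.random.default_rng(params.seed)
    layout = params.layout()
    n_a, n_f = params.n_arenas, params.duration
    a_major = max(params.fly_semi_axes)
    margin = a_major + 1.0
    r_allowed = params.arena_radius - margin

    asleep = _sleep_mask(params)
    x = np.empty((n_a, n_f))
    y = np.empty((n_a, n_f))
    hd = np.empty((n_a, n_f))  # radians internally

    for a in range(n_a):
        cx, cy = layout.centers[a]
        rho = 0.5 * r_allowed * np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        px, py = cx + rho * np.cos(phi), cy + rho * np.sin(phi)
        theta = rng.uniform(0, 2 * np.pi)
        x[a, 0], y[a, 0], hd[a, 0] = px, py, theta
        for f in range(1, n_f):
            if asleep[a, f]:
                x[a, f], y[a, f], hd[a, f] = px, py, theta
                continue
            theta = theta + rng.normal(0.0, params.turn_sd)
            step = max(0.0, rng.normal(params.speed_mean, params.speed_sd))
            nx, ny = px + step * np.cos(theta), py + step * np.sin(theta)
            if np.hypot(nx - cx, ny - cy) > r_allowed:
                # specular reflection about the tangent at the wall
                nrm = np.array([px - cx, py - cy])
                nn = np.hypot(*nrm)
                if nn > 0:
                    nrm /= nn
                    v = np.array([np.cos(theta), np.sin(theta)])
                    v = v - 2.0 * (v @ nrm) * nrm
                    theta = float(np.arctan2(v[1], v[0]))
                nx, ny = px + step * np.cos(theta), py + step * np.sin(theta)
                if np.hypot(nx - cx, ny - cy) > r_allowed:
                    nx, ny = px, py  # cornered; wait a frame
            px, py = nx, ny
            theta = theta % (2 * np.pi)
            x[a, f], y[a, f], hd[a, f] = px, py, theta

    return GroundTruth(x=x, y=y, heading_deg=np.degrees(hd) % 360.0, asleep=asleep)


def render_static_scene(params: SynthParams) -> np.ndarray:
    """The true fly-free background: flat field, arena rims, impurities."""
    h, w = params.frame_shape()
    scene = np.full((h, w), params.background_intensity, dtype=np.uint8)
    layout = params.layout()
    if params.draw_rims:
        yy, xx = np.mgrid[0:h, 0:w]
        for (cx, cy), r in zip(layout.centers, layout.radii):
            d = np.hypot(xx - cx, yy - cy)
            scene[np.abs(d - r) <= 0.8] = params.rim_intensity
    if params.impurity_count:
        rng = np.random.default_rng(params.seed + 1_000_003)
        placed = 0
        attempts = 0
        while placed < params.impurity_count and attempts < 10_000:
            attempts += 1
            ix = rng.integers(1, w - 2)
            iy = rng.integers(1, h - 2)
            d = np.hypot(layout.centers[:, 0] - ix, layout.centers[:, 1] - iy)
            if (d <= layout.radii + 3).any():
                continue  # keep specks outside arenas
            size = int(rng.integers(1, 4))  # 1-3 px, below the 4-px body minimum
            offs = [(0, 0), (1, 0), (0, 1)][:size]
            for dx, dy in offs:
                scene[iy + dy, ix + dx] = params.impurity_intensity
            placed += 1
    return scene


def _draw_ellipse(frame: np.ndarray, x: float, y: float, theta_deg: float,
                  semi_axes: tuple[float, float], intensity: int) -> None:
    a, b = semi_axes
    h, w = frame.shape
    ext = max(a, b) + 1.0
    x0, x1 = int(np.floor(x - ext)), int(np.ceil(x + ext)) + 1
    y0, y1 = int(np.floor(y - ext)), int(np.ceil(y + ext)) + 1
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        raise ValueError("fly ellipse would exit frame bounds")
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = xx - x
    dy = yy - y
    th = np.radians(theta_deg)
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    frame[y0:y1, x0:x1][inside] = intensity


def render_video(truth: GroundTruth, params: SynthParams) -> tuple[ArrayFrameStream, ArenaLayout]:
    """Rasterize the ground truth into a grayscale frame stream.

    Each frame is the static scene plus one filled ellipse per arena at
    the true position with major axis along the true heading, plus
    optional clipped Gaussian pixel noise.
    """
    if truth.n_arenas != params.n_arenas or truth.frame_count != params.duration:
        raise ValueError("ground truth inconsistent with params")
    scene = render_static_scene(params)
    layout = params.layout()
    n_f = params.duration
    frames = np.empty((n_f, *scene.shape), dtype=np.uint8)
    noise_rng = np.random.default_rng(params.seed + 2_000_003)
    for f in range(n_f):
        frame = scene.copy()
        for a in range(params.n_arenas):
            _draw_ellipse(frame, truth.x[a, f], truth.y[a, f], truth.heading_deg[a, f],
                          params.fly_semi_axes, params.fly_intensity)
        if params.noise_sd > 0:
            noisy = frame.astype(np.float64) + noise_rng.normal(0.0, params.noise_sd, frame.shape)
            frame = np.clip(np.round(noisy), 0, 255).astype(np.uint8)
        frames[f] = frame
    return ArrayFrameStream(frames, params.fps), layout


def simulate(params: SynthParams) -> tuple[GroundTruth, ArrayFrameStream, ArenaLayout]:
    """Ground truth plus rendered video in one call."""
    truth = simulate_trajectory(params)
    stream, layout = render_video(truth, params)
    return truth, stream, layout


def write_fixture(
    stream: ArrayFrameStream,
    truth: GroundTruth,
    layout: ArenaLayout,
    out_dir: str | os.PathLike,
    groups: dict[int, str] | None = None,
    config_overrides: dict | None = None,
) -> dict[str, Path]:
    """Write a complete on-disk fixture: frames, truth, layout, group table, config.

    Frames go to a lossless PNG folder (bit-exact round trip); the
    emitted ``config.yaml`` points at the written inputs and parses via
    :func:`flyarena.config_io.load_config`.
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    frames_dir = out_dir / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    ndigits = max(5, len(str(stream.frame_count)))
    for i in range(stream.frame_count):
        iio.imwrite(frames_dir / f"frame_{i:0{ndigits}d}.png", stream.frame(i))
    with open(frames_dir / "meta.yaml", "w") as fh:
        yaml.safe_dump({"fps": stream.fps}, fh)

    truth_csv = out_dir / "ground_truth.csv"
    truth.to_frame().to_csv(truth_csv, index=False)
    layout_csv = out_dir / "layout.csv"
    layout.to_frame().to_csv(layout_csv, index=False)

    group_csv = out_dir / "group.csv"
    if groups is None:
        n = len(layout)
        if n >= 4:  # split into two pseudo-treatments so group stats are defined
            groups = {a: ("control" if a < n // 2 else "treatment") for a in range(n)}
        else:
            groups = {a: "all" for a in range(n)}
    pd.DataFrame(
        {"fly_id": sorted(groups), "group": [groups[a] for a in sorted(groups)]}
    ).to_csv(group_csv, index=False)

    cfg = RunConfig(
        video_path=str(frames_dir),
        group_path=str(group_csv),
        output_dir=str(out_dir / "output"),
        fps_override=stream.fps,
    )
    cfg.arena.mode = "manual"
    cfg.arena.centers = [tuple(c) for c in layout.centers]
    cfg.arena.radius = float(layout.radii[0])
    if config_overrides:
        for k, v in config_overrides.items():
            setattr(cfg, k, v)
        cfg.validate()
    config_path = write_config(cfg, out_dir / "config.yaml")

    return {
        "frames": frames_dir,
        "ground_truth": truth_csv,
        "layout": layout_csv,
        "groups": group_csv,
        "config": config_path,
    }
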