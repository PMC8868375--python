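"""Run configuration, group tables, and video input.

Conventions used throughout the package:

* Coordinates are 0-based pixel indices, origin at the top-left corner,
  x increasing rightward and y increasing downward. Sub-pixel centroids
  are fractional (x, y) pairs in the same frame.
* Angles are measured in degrees from the +x axis toward +y (i.e.
  clockwise on screen since y points down). Body-axis angles live in
  [0, 180), headings (tail-to-head) in [0, 360).
* Time-to-frame conversion is ``frame = floor(t * fps)``; every bin is
  defined in whole frames internally so repeated conversions cannot
  drift.
* Distances are reported in pixels; when ``mm_per_px`` is configured,
  millimetre columns are added alongside (never replacing) the pixel
  columns.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RunConfig",
    "ArenaConfig",
    "load_config",
    "write_config",
    "load_groups",
    "open_video",
    "FrameStream",
    "ArrayFrameStream",
    "FolderFrameStream",
    "TiffFrameStream",
]

#: default thresholds of the segmentation rule: a pixel is fly if its
#: value is below FG_MAX_VALUE and the background exceeds it by more
#: than BG_MIN_DIFF.
FG_MAX_VALUE = 120
BG_MIN_DIFF = 70
#: smallest connected component accepted as a fly body, in pixels.
MIN_AREA = 4
#: number of randomly sampled frames used for background modeling.
N_BG_FRAMES = 800

VIDEO_SUFFIXES = {".mp4", ".avi", ".mov", ".flv"}


@dataclass
class ArenaConfig:
    """Arena-layout block of the run configuration.

    ``mode="manual"`` takes explicit circle centers (or a regular
    rows x cols grid); ``mode="auto"`` asks the tracker to detect
    circular rims on the background image.
    """

    mode: str = "manual"
    rows: int | None = None
    cols: int | None = None
    radius: float | None = None
    spacing: float | None = None
    origin: tuple[float, float] | None = None
    centers: list[tuple[float, float]] | None = None

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"mode": self.mode}
        if self.rows is not None:
            d["rows"] = self.rows
        if self.cols is not None:
            d["cols"] = self.cols
        if self.radius is not None:
            d["radius"] = self.radius
        if self.spacing is not None:
            d["spacing"] = self.spacing
        if self.origin is not None:
            d["origin"] = [float(self.origin[0]), float(self.origin[1])]
        if self.centers is not None:
            d["centers"] = [[float(x), float(y)] for x, y in self.centers]
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ArenaConfig":
        kw = dict(d)
        mode = kw.pop("mode", "manual")
        if mode not in ("manual", "auto"):
            raise ValueError(f"arena.mode must be 'manual' or 'auto', got {mode!r}")
        origin = kw.pop("origin", None)
        if origin is not None:
            origin = (float(origin[0]), float(origin[1]))
        centers = kw.pop("centers", None)
        if centers is not None:
            centers = [(float(c[0]), float(c[1])) for c in centers]
        known = {"rows", "cols", "radius", "spacing"}
        extra = set(kw) - known
        if extra:
            raise ValueError(f"unknown arena keys: {sorted(extra)}")
        return cls(mode=mode, origin=origin, centers=centers, **kw)


@dataclass
class RunConfig:
    """Resolved run configuration with all defaults filled in.

    Unknown keys found in the YAML file are preserved in ``extras`` and
    echoed verbatim into the output config, so user annotations survive
    a run.
    """

    video_path: str = ""
    group_path: str = ""
    output_dir: str = "output"
    fps_override: float | None = None
    analysis_start: float | None = None  # seconds into the video
    analysis_end: float | None = None
    fg_max_value: int = FG_MAX_VALUE
    bg_min_diff: int = BG_MIN_DIFF
    min_area: int = MIN_AREA
    n_bg_frames: int = N_BG_FRAMES
    seed: int = 0
    dist_bin: float = 600.0  # seconds
    sleep_bin: float = 1800.0  # seconds
    sleep_min_duration: float = 300.0  # seconds; bouts must be strictly longer
    eps_still: float = 1.0  # px/frame below which a fly counts as inactive
    speed_min: float = 1.0  # px/frame below which heading polarity is carried
    heatmap_remove_sleep: bool = False
    angle_mode: str = "path"  # "path" (movement direction) or "body"
    region_bins: int = 3
    control_group: str | None = None
    mm_per_px: float | None = None
    alpha: float = 0.05
    arena: ArenaConfig = field(default_factory=ArenaConfig)
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for key in ("fg_max_value", "bg_min_diff"):
            v = getattr(self, key)
            if not (0 <= v <= 255):
                raise ValueError(f"{key} must be in [0, 255], got {v}")
        if self.min_area < 1:
            raise ValueError(f"min_area must be >= 1, got {self.min_area}")
        if self.n_bg_frames < 1:
            raise ValueError(f"n_bg_frames must be >= 1, got {self.n_bg_frames}")
        for key in ("dist_bin", "sleep_bin", "sleep_min_duration"):
            v = getattr(self, key)
            if v <= 0:
                raise ValueError(f"{key} must be > 0, got {v}")
        if (
            self.analysis_start is not None
            and self.analysis_end is not None
            and not self.analysis_start < self.analysis_end
        ):
            raise ValueError(
                "analysis_start must be < analysis_end "
                f"(got {self.analysis_start} >= {self.analysis_end})"
            )
        if self.angle_mode not in ("path", "body"):
            raise ValueError(f"angle_mode must be 'path' or 'body', got {self.angle_mode!r}")
        if self.region_bins < 2:
            raise ValueError(f"region_bins must be >= 2, got {self.region_bins}")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d.pop("extras")
        d["arena"] = self.arena.to_dict()
        d = {k: v for k, v in d.items() if v is not None}
        d.update(self.extras)
        return d


_CONFIG_FIELDS = {
    f for f in RunConfig.__dataclass_fields__ if f not in ("extras", "arena")
}


def load_config(path: str | os.PathLike) -> RunConfig:
    """Parse a YAML run configuration, filling defaults for absent keys."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ValueError(f"config file {path} is not valid YAML: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must be a mapping at top level")
    return config_from_dict(raw)


def config_from_dict(raw: dict[str, Any]) -> RunConfig:
    kwargs: dict[str, Any] = {}
    extras: dict[str, Any] = {}
    for key, value in raw.items():
        if key == "arena":
            kwargs["arena"] = ArenaConfig.from_dict(value or {})
        elif key in _CONFIG_FIELDS:
            kwargs[key] = value
        else:
            extras[key] = value
    try:
        cfg = RunConfig(extras=extras, **kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc
    return cfg


def write_config(config: RunConfig, path: str | os.PathLike) -> Path:
    """Write the resolved configuration back out as YAML (the config echo)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True, default_flow_style=False)
    return path


# ---------------------------------------------------------------------------
# group table


def load_groups(path: str | os.PathLike) -> pd.DataFrame:
    """Load the fly-to-treatment assignment table.

    Accepts an XLSX workbook (sheet 1) or a CSV, either with columns
    ``fly_id`` (0-based arena index) and ``group`` (treatment label).
    Returns a DataFrame with those two columns, labels stripped of
    surrounding whitespace.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"group table not found: {path}")
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, sheet_name=0)
    else:
        df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    colmap = {}
    for want, aliases in (("fly_id", ("fly_id", "fly", "arena")), ("group", ("group", "treatment", "label"))):
        for a in aliases:
            if a in df.columns:
                colmap[a] = want
                break
        else:
            raise ValueError(f"group table {path} lacks a '{want}' column")
    df = df.rename(columns=colmap)[["fly_id", "group"]]
    if len(df) == 0:
        raise ValueError(f"group table {path} is empty")
    fly = pd.to_numeric(df["fly_id"], errors="coerce")
    if fly.isna().any() or (fly < 0).any() or (fly != fly.astype(int)).any():
        raise ValueError("fly_id values must be non-negative integers")
    df["fly_id"] = fly.astype(int)
    if df["fly_id"].duplicated().any():
        dupes = sorted(df.loc[df["fly_id"].duplicated(), "fly_id"].unique())
        raise ValueError(f"duplicate fly_id values in group table: {dupes}")
    df["group"] = df["group"].astype(str).str.strip()
    if (df["group"] == "").any():
        raise ValueError("empty group labels in group table")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# frame streams


class FrameStream:
    """Ordered grayscale frames with fps and dimensions.

    Subclasses implement :meth:`frame`. Intensities are uint8.
    """

    frame_count: int
    fps: float
    height: int
    width: int

    def frame(self, i: int) -> np.ndarray:
        raise NotImplementedError

    def __len__(self) -> int:
        return self.frame_count

    def __iter__(self) -> Iterator[np.ndarray]:
        for i in range(self.frame_count):
            yield self.frame(i)


def _to_gray(img: np.ndarray) -> np.ndarray:
    """Standard luma conversion (ITU-R BT.601 weights) for color frames."""
    if img.ndim == 2:
        return img.astype(np.uint8, copy=False)
    if img.ndim == 3 and img.shape[2] in (3, 4):
        rgb = img[..., :3].astype(np.float64)
        gray = rgb @ np.array([0.299, 0.587, 0.114])
        return np.clip(np.round(gray), 0, 255).astype(np.uint8)
    raise ValueError(f"unsupported frame shape {img.shape}")


class ArrayFrameStream(FrameStream):
    """In-memory stream over a (frames, height, width) uint8 array."""

    def __init__(self, frames: np.ndarray, fps: float):
        frames = np.asarray(frames)
        if frames.ndim != 3:
            raise ValueError("expected a (frames, height, width) array")
        if frames.shape[0] == 0:
            raise ValueError("empty frame array")
        if fps <= 0:
            raise ValueError(f"fps must be > 0, got {fps}")
        self._frames = frames.astype(np.uint8, copy=False)
        self.frame_count, self.height, self.width = frames.shape
        self.fps = float(fps)

    def frame(self, i: int) -> np.ndarray:
        return self._frames[i]


class FolderFrameStream(FrameStream):
    """Stream over a directory of numbered lossless image frames.

    The canonical bit-exact video backend: one PNG per frame, sorted by
    filename, with fps taken from a ``meta.yaml`` sidecar or from the
    configuration's ``fps_override``.
    """

    def __init__(self, folder: str | os.PathLike, fps: float | None = None):
        import imageio.v3 as iio

        self._iio = iio
        folder = Path(folder)
        self._paths = sorted(
            p for p in folder.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not self._paths:
            raise ValueError(f"no frame images found in {folder}")
        meta = folder / "meta.yaml"
        if fps is None and meta.is_file():
            with open(meta) as fh:
                fps = float(yaml.safe_load(fh).get("fps", 0))
        if fps is None or fps <= 0:
            raise ValueError(
                f"fps unknown for frame folder {folder}; provide fps_override or meta.yaml"
            )
        first = _to_gray(iio.imread(self._paths[0]))
        self.height, self.width = first.shape
        self.frame_count = len(self._paths)
        self.fps = float(fps)
        self._cache0 = first

    def frame(self, i: int) -> np.ndarray:
        if i == 0:
            return self._cache0
        img = _to_gray(self._iio.imread(self._paths[i]))
        if img.shape != (self.height, self.width):
            raise ValueError(f"frame {i} has shape {img.shape}, expected {(self.height, self.width)}")
        return img


class TiffFrameStream(ArrayFrameStream):
    """Stream over a multi-page TIFF stack (lossless)."""

    def __init__(self, path: str | os.PathLike, fps: float):
        import imageio.v3 as iio

        arr = iio.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim == 4:
            arr = np.stack([_to_gray(f) for f in arr])
        super().__init__(arr, fps)


class _ImageioVideoStream(FrameStream):
    """Container video (MP4/AVI/MOV/FLV) decoded through imageio.

    Requires an ffmpeg-capable imageio plugin at run time; frames are
    decoded fully into memory so indexed access is deterministic.
    """

    def __init__(self, path: str | os.PathLike, fps: float | None = None):
        import imageio.v3 as iio

        path = Path(path)
        try:
            props = iio.improps(path, plugin="pyav")
            plugin = "pyav"
        except Exception:
            plugin = None
        try:
            frames = iio.imread(path, plugin=plugin) if plugin else iio.imread(path)
        except Exception as exc:
            raise ValueError(
                f"could not decode video {path}: {exc}. "
                "Install an ffmpeg-capable imageio plugin or convert the video "
                "to a lossless frame folder / TIFF stack."
            ) from exc
        if fps is None:
            try:
                meta = iio.immeta(path)
                fps = float(meta.get("fps", 0)) or None
            except Exception:
                fps = None
        if fps is None:
            raise ValueError(f"container fps unavailable for {path}; set fps_override")
        frames = np.asarray(frames)
        if frames.ndim == 3 and frames.shape[-1] in (3, 4):
            frames = frames[None]
        gray = np.stack([_to_gray(f) for f in frames])
        self._inner = ArrayFrameStream(gray, fps)
        self.frame_count = self._inner.frame_count
        self.fps = self._inner.fps
        self.height = self._inner.height
        self.width = self._inner.width

    def frame(self, i: int) -> np.ndarray:
        return self._inner.frame(i)


def open_video(path: str | os.PathLike, config: RunConfig | None = None) -> FrameStream:
    """Open a video input as a grayscale :class:`FrameStream`.

    ``path`` may be a directory of lossless frames, a multi-page TIFF,
    or a video container. ``config.fps_override`` takes precedence over
    any fps stored with the input.
    """
    path = Path(path)
    fps_override = config.fps_override if config is not None else None
    if path.is_dir():
        return FolderFrameStream(path, fps=fps_override)
    if not path.exists():
        raise FileNotFoundError(f"video not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        if fps_override is None:
            raise ValueError("TIFF stacks carry no fps; set fps_override in the config")
        return TiffFrameStream(path, fps=fps_override)
    if suffix in VIDEO_SUFFIXES:
        return _ImageioVideoStream(path, fps=fps_override)
    raise ValueError(f"unsupported video input {path} (suffix {suffix!r})")


def analysis_window(config: RunConfig, stream: FrameStream) -> tuple[int, int]:
    """Resolve the configured analysis window to a half-open frame range."""
    start = 0 if config.analysis_start is None else int(np.floor(config.analysis_start * stream.fps))
    end = (
        stream.frame_count
        if config.analysis_end is None
        else min(stream.frame_count, int(np.floor(config.analysis_end * stream.fps)))
    )
    start = max(0, start)
    if start >= end:
        raise ValueError(f"empty analysis window: frames [{start}, {end})")
    return start, end
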