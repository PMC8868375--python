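"""Behavioral statistics computed from trajectories.

Implements the assay's standard read-outs: locomotor activity as
distance travelled in fixed time bins (default 10 min), sleep as
maximal immobility runs strictly longer than 5 min, turning as mean
absolute angle change per second, occupancy heatmaps per arena and per
group, and regional (center-to-rim) preference.

All statistics operate on carried positions: frames with no detection
repeat the last valid position and therefore contribute zero
displacement, which deliberately biases gaps toward "inactive". Time
bins are fixed frame counts (``floor(bin_seconds * fps)``); a trailing
partial bin is dropped rather than rescaled so bins stay comparable
across flies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .arenas import ArenaLayout, TrajectorySet

__all__ = [
    "frame_displacements",
    "bin_distances",
    "detect_sleep",
    "asleep_mask",
    "sleep_status",
    "angle_change",
    "mean_angle_change",
    "occupancy_heatmap",
    "normalize_heatmap",
    "group_heatmap",
    "regional_preference",
]

Bouts = list[tuple[int, int]]  # half-open frame ranges


def frame_displacements(traj: TrajectorySet) -> np.ndarray:
    """Per-frame displacement magnitude, (arenas, frames); frame 0 is 0."""
    dx = np.diff(traj.x, axis=1, prepend=traj.x[:, :1])
    dy = np.diff(traj.y, axis=1, prepend=traj.y[:, :1])
    return np.hypot(dx, dy)


def bin_distances(traj: TrajectorySet, dist_bin: float, mm_per_px: float | None = None) -> pd.DataFrame:
    """Distance travelled per fixed time bin, per arena.

    ``dist_bin`` is the bin length in seconds. Returns a tidy frame
    with columns ``arena, bin, start_s, end_s, distance_px`` (and
    ``distance_mm`` when a scale is given).
    """
    bin_frames = int(np.floor(dist_bin * traj.fps))
    if bin_frames < 1:
        raise ValueError(f"dist_bin of {dist_bin}s is shorter than one frame")
    disp = frame_displacements(traj)
    n_bins = traj.frame_count // bin_frames
    rows = []
    for a in range(traj.n_arenas):
        for b in range(n_bins):
            lo, hi = b * bin_frames, (b + 1) * bin_frames
            rows.append(
                {
                    "arena": a,
                    "bin": b,
                    "start_s": lo / traj.fps,
                    "end_s": hi / traj.fps,
                    "distance_px": float(disp[a, lo:hi].sum()),
                }
            )
    df = pd.DataFrame(rows, columns=["arena", "bin", "start_s", "end_s", "distance_px"])
    if mm_per_px is not None:
        df["distance_mm"] = df["distance_px"] * mm_per_px
    return df


def detect_sleep(traj: TrajectorySet, sleep_min_duration: float = 300.0,
                 eps_still: float = 1.0) -> list[Bouts]:
    """Sleep bouts per arena: maximal immobility runs strictly longer than the threshold.

    A frame counts as still when its displacement from the previous
    frame is below ``eps_still`` px (carried/invalid frames are still
    by construction). A maximal run of still frames is a bout only if
    its duration strictly exceeds ``sleep_min_duration`` seconds —
    immobility of exactly the threshold does not qualify. Bouts are
    half-open ``(start_frame, end_frame)`` ranges.
    """
    if eps_still < 0:
        raise ValueError("eps_still must be >= 0")
    disp = frame_displacements(traj)
    min_frames = sleep_min_duration * traj.fps  # strict: run must exceed this
    all_bouts: list[Bouts] = []
    for a in range(traj.n_arenas):
        still = disp[a, 1:] < eps_still  # still[f-1]: frame f did not move vs f-1
        bouts: Bouts = []
        f = 0
        n = len(still)
        while f < n:
            if still[f]:
                start = f
                while f < n and still[f]:
                    f += 1
                run = f - start
                if run > min_frames:
                    bouts.append((start + 1, f + 1))
            else:
                f += 1
        all_bouts.append(bouts)
    return all_bouts


def asleep_mask(bouts: Bouts, frame_count: int) -> np.ndarray:
    """Boolean per-frame asleep flag from a bout list."""
    m = np.zeros(frame_count, dtype=bool)
    for s, e in bouts:
        m[s:e] = True
    return m


def sleep_status(
    all_bouts: list[Bouts],
    group_table: pd.DataFrame,
    sleep_bin: float,
    fps: float,
    frame_count: int,
) -> pd.DataFrame:
    """Per-time-bin, per-group sleep summary.

    For each bin (default 30 min) and group: the mean number of asleep
    seconds per fly, and the fraction of flies with at least one asleep
    frame in the bin. Incomplete trailing bins are dropped.
    """
    bin_frames = int(np.floor(sleep_bin * fps))
    if bin_frames < 1:
        raise ValueError(f"sleep_bin of {sleep_bin}s is shorter than one frame")
    n_bins = frame_count // bin_frames
    missing = [int(f) for f in group_table["fly_id"] if f >= len(all_bouts)]
    if missing:
        raise ValueError(f"group table references arenas with no trajectory: {missing}")
    rows = []
    for group, members in group_table.groupby("group")["fly_id"]:
        masks = [asleep_mask(all_bouts[int(a)], frame_count) for a in members]
        for b in range(n_bins):
            lo, hi = b * bin_frames, (b + 1) * bin_frames
            asleep_frames = np.array([m[lo:hi].sum() for m in masks])
            rows.append(
                {
                    "group": group,
                    "bin": b,
                    "start_s": lo / fps,
                    "end_s": hi / fps,
                    "mean_sleep_s": float(asleep_frames.mean() / fps),
                    "frac_asleep": float((asleep_frames > 0).mean()),
                }
            )
    return pd.DataFrame(rows, columns=["group", "bin", "start_s", "end_s", "mean_sleep_s", "frac_asleep"])


def _circ_diff_deg(a, b):
    d = np.abs(np.asarray(a) - np.asarray(b)) % 360.0
    return np.minimum(d, 360.0 - d)


def angle_change(traj: TrajectorySet, eps_still: float = 1.0, mode: str = "path") -> pd.DataFrame:
    """Absolute angle change per second, per arena.

    The angle is sampled once per second (frame stride ``round(fps)``).
    ``mode="path"`` (default) uses the movement direction — the angle of
    the displacement over each one-second interval — which is robust to
    head/tail polarity errors; ``mode="body"`` uses the resolved body
    heading instead. Seconds whose sampled displacement is below
    ``eps_still`` px, or whose angle is undefined, are excluded, so a
    stationary fly reports no values rather than zeros.

    Returns a tidy frame ``arena, second, change_deg`` with change
    values in [0, 180]; see :func:`mean_angle_change` for the per-arena
    summary.
    """
    if mode not in ("path", "body"):
        raise ValueError(f"mode must be 'path' or 'body', got {mode!r}")
    stride = max(1, int(round(traj.fps)))
    idx = np.arange(0, traj.frame_count, stride)
    rows = []
    for a in range(traj.n_arenas):
        xs, ys = traj.x[a, idx], traj.y[a, idx]
        dx, dy = np.diff(xs), np.diff(ys)
        disp = np.hypot(dx, dy)
        if mode == "path":
            ang = np.degrees(np.arctan2(dy, dx)) % 360.0
        else:
            ang = traj.heading[a, idx[1:]].copy()
        ang[disp < eps_still] = np.nan
        for i in range(1, len(ang)):
            if np.isnan(ang[i]) or np.isnan(ang[i - 1]):
                continue
            rows.append(
                {"arena": a, "second": i, "change_deg": float(_circ_diff_deg(ang[i], ang[i - 1]))}
            )
    return pd.DataFrame(rows, columns=["arena", "second", "change_deg"])


def mean_angle_change(traj: TrajectorySet, eps_still: float = 1.0, mode: str = "path") -> pd.Series:
    """Per-arena mean per-second angle change; NaN where every second was excluded."""
    df = angle_change(traj, eps_still=eps_still, mode=mode)
    means = df.groupby("arena")["change_deg"].mean()
    return means.reindex(range(traj.n_arenas))


def occupancy_heatmap(
    traj: TrajectorySet,
    layout: ArenaLayout,
    remove_sleep: bool = False,
    all_bouts: list[Bouts] | None = None,
) -> dict[int, np.ndarray]:
    """Visit counts over each arena's bounding box, one grid per arena.

    Each counted frame increments the cell under the rounded centroid,
    so counts sum to the number of counted frames. ``remove_sleep``
    drops exactly the frames inside detected sleep bouts.
    """
    if remove_sleep and all_bouts is None:
        raise ValueError("remove_sleep requires detected bouts")
    grids: dict[int, np.ndarray] = {}
    for a in range(traj.n_arenas):
        r = int(np.ceil(layout.radii[a]))
        side = 2 * r + 1
        cx, cy = layout.centers[a]
        x0, y0 = int(round(cx)) - r, int(round(cy)) - r
        grid = np.zeros((side, side), dtype=np.int64)
        counted = np.ones(traj.frame_count, dtype=bool)
        if remove_sleep:
            counted &= ~asleep_mask(all_bouts[a], traj.frame_count)
        xs = np.round(traj.x[a, counted]).astype(int) - x0
        ys = np.round(traj.y[a, counted]).astype(int) - y0
        inb = (xs >= 0) & (xs < side) & (ys >= 0) & (ys < side)
        np.add.at(grid, (ys[inb], xs[inb]), 1)
        grids[a] = grid
    return grids


def normalize_heatmap(grid: np.ndarray) -> np.ndarray:
    """Scale counts so the maximum is 1 (all-zero grids stay zero)."""
    m = grid.max()
    return grid.astype(float) / m if m > 0 else grid.astype(float)


def group_heatmap(grids: dict[int, np.ndarray], group_table: pd.DataFrame) -> dict[str, np.ndarray]:
    """Sum per-arena grids within each group, aligned by arena center.

    Grids of unequal size are centered onto the largest; chambers are
    rotationally symmetric, so translation-only alignment suffices.
    """
    out: dict[str, np.ndarray] = {}
    for group, members in group_table.groupby("group")["fly_id"]:
        member_grids = [grids[int(a)] for a in members if int(a) in grids]
        if not member_grids:
            continue
        side = max(g.shape[0] for g in member_grids)
        total = np.zeros((side, side), dtype=np.int64)
        for g in member_grids:
            off = (side - g.shape[0]) // 2
            total[off : off + g.shape[0], off : off + g.shape[1]] += g
        out[group] = total
    return out


def regional_preference(traj: TrajectorySet, layout: ArenaLayout, k: int = 3) -> pd.DataFrame:
    """Occupancy fraction in K equal-width radial bins (center to rim), per arena.

    Each frame is binned by its normalized radial distance
    ``|(x, y) - center| / r``; fractions over the K bins sum to 1.
    Positions at or beyond the rim fall in the outermost bin.
    """
    if k < 2:
        raise ValueError(f"need at least 2 radial bins, got {k}")
    rows = []
    for a in range(traj.n_arenas):
        cx, cy = layout.centers[a]
        r = layout.radii[a]
        rho = np.hypot(traj.x[a] - cx, traj.y[a] - cy) / r
        bins = np.minimum((rho * k).astype(int), k - 1)
        counts = np.bincount(bins, minlength=k)
        frac = counts / counts.sum() if counts.sum() else counts.astype(float)
        for b in range(k):
            rows.append({"arena": a, "radial_bin": b, "fraction": float(frac[b])})
    return pd.DataFrame(rows, columns=["arena", "radial_bin", "fraction"])
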