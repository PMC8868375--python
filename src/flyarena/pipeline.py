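"""End-to-end orchestration: config in, trajectories and reports out.

Thin glue over the library modules so the CLI and scripts share one
code path. ``run_track`` produces (and dumps) trajectories;
``run_analyze`` turns them into the behavioral statistics, group
comparisons, plots, and the output bundle.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import report
from .arenas import TrajectorySet, build_layout, load_trajectories, save_trajectories, track
from .background import estimate_background
from .config_io import RunConfig, load_config, load_groups, open_video

__all__ = ["run_track", "run_analyze", "run_all"]


def run_track(config: RunConfig, seed: int | None = None) -> TrajectorySet:
    """Open the video, model the background, build the layout, track.

    Dumps the background image and the trajectory arrays into
    ``config.output_dir`` so analysis can be rerun without retracking.
    """
    if seed is not None:
        config.seed = seed
    stream = open_video(config.video_path, config)
    bg = estimate_background(stream, config.n_bg_frames, config.seed)
    layout = build_layout(config, bg)
    traj = track(stream, bg, layout, config)

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    import imageio.v3 as iio

    iio.imwrite(out_dir / "background.png", bg)
    save_trajectories(traj, out_dir)
    layout.to_frame().to_csv(out_dir / "layout.csv", index=False)
    np.save(out_dir / "tracking_meta.npy",
            np.array([traj.fps, traj.frame_offset]))
    return traj


def run_analyze(config: RunConfig, traj: TrajectorySet | None = None):
    """Behavioral statistics + group comparison + output bundle.

    Reloads trajectories dumped by :func:`run_track` when none are
    passed in.
    """
    out_dir = Path(config.output_dir)
    if traj is None:
        npy = out_dir / "trajectories.npy"
        if not npy.is_file():
            raise FileNotFoundError(f"no trajectories at {npy}; run tracking first")
        fps, offset = np.load(out_dir / "tracking_meta.npy")
        traj = load_trajectories(npy, fps=float(fps), frame_offset=int(offset))
    if traj.layout is None:
        from .arenas import ArenaLayout
        import pandas as pd

        traj.layout = ArenaLayout.from_frame(pd.read_csv(out_dir / "layout.csv"))
    group_table = load_groups(config.group_path)
    results = report.analyze(traj, traj.layout, group_table, config)
    manifest = report.render_outputs(results, traj, traj.layout, group_table, config, out_dir)
    return results, manifest


def run_all(config_path: str, seed: int | None = None):
    """Convenience: track then analyze from a config file path."""
    config = load_config(config_path)
    traj = run_track(config, seed=seed)
    return run_analyze(config, traj)
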