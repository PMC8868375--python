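"""Shared fixtures: synthetic recordings with exact ground truth."""

from __future__ import annotations

import numpy as np
import pytest

import flyarena as fa
from flyarena.config_io import ArenaConfig, RunConfig


def layout_config(layout, **overrides) -> RunConfig:
    """RunConfig whose manual arena block matches a simulator layout."""
    cfg = RunConfig(
        arena=ArenaConfig(
            mode="manual",
            centers=[tuple(c) for c in layout.centers],
            radius=float(layout.radii[0]),
        ),
        **overrides,
    )
    return cfg


@pytest.fixture(scope="session")
def small_recording():
    """Two arenas, 200 frames, noiseless: truth, stream, layout, tracked set."""
    params = fa.SynthParams(rows=1, cols=2, duration=200, fps=10.0, seed=11)
    truth, stream, layout = fa.simulate(params)
    bg = fa.estimate_background(stream, 800, seed=0)
    cfg = layout_config(layout)
    traj = fa.track(stream, bg, layout, cfg)
    return params, truth, stream, layout, traj


@pytest.fixture(scope="session")
def walk_recording():
    """12 arenas, 9,000 frames at 30 fps, noiseless: the tracking-accuracy bed.

    Five minutes of persistent random walk per arena, the scene scaled
    so the whole pipeline runs in seconds while preserving the default
    segmentation conditions (dark ~4+ px fly on a bright field).
    """
    params = fa.SynthParams(
        rows=3, cols=4, duration=9000, fps=30.0,
        arena_radius=20.0, speed_mean=2.5, turn_sd=0.1, seed=42,
    )
    truth, stream, layout = fa.simulate(params)
    bg = fa.estimate_background(stream, 800, seed=0)
    cfg = layout_config(layout)
    traj = fa.track(stream, bg, layout, cfg)
    return params, truth, stream, layout, traj
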