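"""Layout construction, blob-to-arena assignment, and tracking."""

from __future__ import annotations

import numpy as np
import pytest

import flyarena as fa
from flyarena.arenas import ArenaLayout, assign_blobs, detect_circles
from flyarena.config_io import ArenaConfig, ArrayFrameStream, RunConfig, config_from_dict
from flyarena.detect import Blob

from conftest import layout_config


def _blob(x, y, area=10):
    return Blob(area=area, centroid=(x, y), bbox=(int(x), int(y), int(x) + 1, int(y) + 1),
                pixels=np.array([[int(x), int(y)]]))


class TestBuildLayout:
    def test_grid_72_circles_row_major(self):
        cfg = config_from_dict({"arena": {"mode": "manual", "rows": 6, "cols": 12,
                                          "radius": 20, "spacing": 45}})
        layout = fa.build_layout(cfg)
        assert len(layout) == 72
        # row-major: second circle is one spacing to the right
        np.testing.assert_allclose(layout.centers[1] - layout.centers[0], [45, 0])
        np.testing.assert_allclose(layout.centers[12] - layout.centers[0], [0, 45])

    def test_overlapping_circles_rejected(self):
        cfg = config_from_dict(
            {"arena": {"mode": "manual", "centers": [[10, 10], [20, 10]], "radius": 8}}
        )
        with pytest.raises(ValueError, match="overlap"):
            fa.build_layout(cfg)

    def test_out_of_frame_circle_rejected(self):
        cfg = config_from_dict({"arena": {"mode": "manual", "centers": [[5, 5]], "radius": 10}})
        bg = np.full((50, 50), 230, dtype=np.uint8)
        with pytest.raises(ValueError, match="outside"):
            fa.build_layout(cfg, bg)

    def test_auto_detects_rims_within_2px(self):
        params = fa.SynthParams(rows=2, cols=3, duration=1, draw_rims=True, seed=1)
        truth, stream, layout = fa.simulate(params)
        bg = fa.estimate_background(stream, 1, 0)
        cfg = config_from_dict({"arena": {"mode": "auto", "radius": params.arena_radius}})
        found = fa.build_layout(cfg, bg)
        assert len(found) == 6
        err = np.hypot(*(found.centers - layout.centers).T)
        assert err.max() <= 2.0

    def test_auto_without_circles_errors(self):
        cfg = config_from_dict({"arena": {"mode": "auto", "radius": 10}})
        with pytest.raises(ValueError):
            fa.build_layout(cfg, np.full((60, 60), 230, dtype=np.uint8))


class TestAssignBlobs:
    layout = ArenaLayout(np.array([[20.0, 20.0], [60.0, 20.0], [100.0, 20.0], [140.0, 20.0]]),
                         np.full(4, 15.0))

    def test_single_blob_lands_in_its_arena(self):
        chosen = assign_blobs([_blob(102, 22)], self.layout)
        assert chosen[2] is not None
        assert [c for i, c in enumerate(chosen) if i != 2] == [None, None, None]

    def test_largest_blob_wins(self):
        small, big = _blob(18, 20, area=5), _blob(22, 20, area=9)
        chosen = assign_blobs([small, big], self.layout)
        assert chosen[0] is big

    def test_area_tie_breaks_topmost_then_leftmost(self):
        lower, upper = _blob(20, 25, area=5), _blob(20, 15, area=5)
        assert assign_blobs([lower, upper], self.layout)[0] is upper
        left, right = _blob(18, 20, area=5), _blob(22, 20, area=5)
        assert assign_blobs([left, right], self.layout)[0] is left

    def test_outside_all_circles_dropped(self):
        assert assign_blobs([_blob(40, 20)], self.layout) == [None] * 4


class TestTrack:
    def test_stationary_fly_constant_centroid(self):
        # background taken from the fly-free scene: a fly that never moves
        # would otherwise be absorbed into the temporal mode itself
        from flyarena.synthfly import render_static_scene

        p = fa.SynthParams(speed_mean=0.0, speed_sd=0.0, turn_sd=0.0, duration=60, fps=30, seed=2)
        truth, stream, layout = fa.simulate(p)
        bg = render_static_scene(p)
        traj = fa.track(stream, bg, layout, layout_config(layout))
        assert traj.valid.all()
        assert np.ptp(traj.x) == 0.0 and np.ptp(traj.y) == 0.0

    def test_erased_fly_freezes_position(self):
        p = fa.SynthParams(duration=150, fps=30, speed_mean=2.0, seed=3)
        truth, stream, layout = fa.simulate(p)
        frames = np.stack([stream.frame(i) for i in range(150)])
        from flyarena.synthfly import render_static_scene

        scene = render_static_scene(p)
        frames[100:110] = scene  # fly vanishes for frames 100-109
        stream2 = ArrayFrameStream(frames, fps=30)
        bg = fa.estimate_background(stream2, 800, 0)
        traj = fa.track(stream2, bg, layout, layout_config(layout))
        assert not traj.valid[0, 100:110].any()
        assert traj.valid[0, 99] and traj.valid[0, 110]
        np.testing.assert_array_equal(traj.x[0, 100:110], traj.x[0, 99])

    def test_frame_count_conservation_and_carry_inside_arena(self, walk_recording):
        params, truth, stream, layout, traj = walk_recording
        assert traj.x.shape == (len(layout), params.duration)
        for a in range(traj.n_arenas):
            d = np.hypot(traj.x[a] - layout.centers[a][0], traj.y[a] - layout.centers[a][1])
            assert np.all(d <= layout.radii[a] + 1e-9)

    def test_determinism(self, small_recording):
        params, truth, stream, layout, traj = small_recording
        bg = fa.estimate_background(stream, 800, 0)
        traj2 = fa.track(stream, bg, layout, layout_config(layout))
        np.testing.assert_array_equal(traj.x, traj2.x)
        np.testing.assert_array_equal(traj.heading, traj2.heading)
        np.testing.assert_array_equal(traj.valid, traj2.valid)

    def test_analysis_window_restricts_frames(self, small_recording):
        params, truth, stream, layout, _ = small_recording
        bg = fa.estimate_background(stream, 800, 0)
        cfg = layout_config(layout, analysis_start=2.0, analysis_end=10.0)
        traj = fa.track(stream, bg, layout, cfg)
        assert traj.frame_offset == 20
        assert traj.frame_count == 80

    def test_empty_layout_rejected(self, small_recording):
        params, truth, stream, layout, _ = small_recording
        bg = fa.estimate_background(stream, 800, 0)
        empty = ArenaLayout(np.zeros((0, 2)), np.zeros(0))
        with pytest.raises(ValueError):
            fa.track(stream, bg, empty, layout_config(layout))

    def test_save_load_round_trip(self, small_recording, tmp_path):
        from flyarena.arenas import load_trajectories, save_trajectories

        *_, traj = small_recording
        paths = save_trajectories(traj, tmp_path)
        back = load_trajectories(paths["npy"], fps=traj.fps)
        np.testing.assert_array_equal(back.x, traj.x)
        np.testing.assert_array_equal(back.valid, traj.valid)
        nan_match = np.isnan(back.heading) == np.isnan(traj.heading)
        assert nan_match.all()
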