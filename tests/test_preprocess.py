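"""The trajectory-cleaning chain against exact and oracle expectations."""
import numpy as np
import pandas as pd
import pytest

from octokin import (
    ArmSimConfig,
    add_observation_noise,
    render_depth_stack,
    simulate_arm_stride,
)
from octokin.containers import DepthMapStack, TrackTable, TrajectorySet
from octokin.preprocess import (
    filter_z_median,
    lookup_depth,
    preprocess_tracks,
    remove_background,
    remove_outliers,
    smooth_and_fill,
)


def _traj(z, x=None, y=None, valid=None, fps=60.0, role="key", arm="L1"):
    n = len(z)
    xyz = np.zeros((n, 1, 3))
    xyz[:, 0, 0] = x if x is not None else 0.0
    xyz[:, 0, 1] = y if y is not None else 0.0
    xyz[:, 0, 2] = z
    v = np.ones((n, 1), bool) if valid is None else np.asarray(valid)[:, None]
    info = pd.DataFrame({"point_id": ["p0"], "role": [role], "arm": [arm]})
    return TrajectorySet(info, xyz, v, fps)


class TestLookupDepth:
    def test_constant_region(self):
        depth = np.full((1, 30, 30), 100.0, dtype=np.float32)
        stack = DepthMapStack(depth, np.ones_like(depth, bool), 0.5, 60.0)
        df = pd.DataFrame(
            [{"frame": 0, "point_id": "a", "role": "key", "arm": "L1",
              "x_px": 15.2, "y_px": 14.7, "valid": True}]
        )
        traj = lookup_depth(TrackTable(df, 60.0, 0.5), stack)
        assert traj.xyz[0, 0, 2] == 100.0
        assert traj.xyz[0, 0, 0] == pytest.approx(15.2 * 0.5)
        assert traj.xyz[0, 0, 1] == pytest.approx(14.7 * 0.5)

    def test_spiked_pixel_does_not_move_median(self):
        depth = np.full((1, 30, 30), 100.0, dtype=np.float32)
        depth[0, 15, 15] += 50.0
        stack = DepthMapStack(depth, np.ones_like(depth, bool), 0.5, 60.0)
        df = pd.DataFrame(
            [{"frame": 0, "point_id": "a", "role": "key", "arm": "L1",
              "x_px": 15.0, "y_px": 15.0, "valid": True}]
        )
        traj = lookup_depth(TrackTable(df, 60.0, 0.5), stack)
        assert traj.xyz[0, 0, 2] == 100.0

    def test_mostly_invalid_window_drops_observation(self):
        depth = np.full((1, 30, 30), 100.0, dtype=np.float32)
        valid = np.zeros_like(depth, bool)
        valid[0, 13:18, 13:18] = True  # 25 of 121 pixels
        stack = DepthMapStack(depth, valid, 0.5, 60.0)
        df = pd.DataFrame(
            [{"frame": 0, "point_id": "a", "role": "key", "arm": "L1",
              "x_px": 15.0, "y_px": 15.0, "valid": True}]
        )
        traj = lookup_depth(TrackTable(df, 60.0, 0.5), stack)
        assert not traj.valid[0, 0]

    def test_even_window_rejected(self, short_stride):
        _, traj, _ = short_stride
        stack, tracks = render_depth_stack(traj, 0.5)
        with pytest.raises(ValueError):
            lookup_depth(tracks, stack, window=10)


class TestZMedian:
    def test_constant_unchanged_and_spike_removed(self):
        z = np.full(50, 20.0)
        assert np.array_equal(filter_z_median(_traj(z)).xyz[:, 0, 2], z)
        z2 = z.copy()
        z2[25] = 40.0
        out = filter_z_median(_traj(z2))
        assert out.xyz[25, 0, 2] == 20.0

    def test_xy_untouched(self, rng):
        z = rng.normal(size=40)
        x = rng.normal(size=40)
        out = filter_z_median(_traj(z, x=x))
        assert np.array_equal(out.xyz[:, 0, 0], x)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            filter_z_median(_traj(np.zeros(10)), window=4)


class TestRemoveBackground:
    def _scene(self, n=60, drift=None):
        info = pd.DataFrame(
            {
                "point_id": ["k0", "k1", "r0", "r1", "r2"],
                "role": ["key", "key", "reference", "reference", "reference"],
                "arm": ["L1", "L1", "none", "none", "none"],
            }
        )
        xyz = np.zeros((n, 5, 3))
        xyz[:, 0] = (0.0, 0.0, 100.0)
        xyz[:, 1] = (10.0, 5.0, 110.0)
        xyz[:, 2] = (50.0, 50.0, 100.0)
        xyz[:, 3] = (-50.0, 50.0, 100.0)
        xyz[:, 4] = (0.0, -50.0, 100.0)
        clean = xyz.copy()
        if drift is not None:
            xyz = xyz + drift[:, None, :]
        return (
            TrajectorySet(info, xyz, np.ones((n, 5), bool), 60.0),
            clean,
        )

    def test_translation_recovered_exactly(self, rng):
        drift = rng.normal(size=(60, 3)) * 10
        drift[0] = 0.0  # anchor frame
        traj, clean = self._scene(drift=drift)
        out = remove_background(traj)
        assert np.max(np.abs(out.xyz - clean)) < 1e-9

    def test_zero_drift_identity(self):
        traj, clean = self._scene()
        out = remove_background(traj)
        assert np.array_equal(out.xyz, clean)

    def test_idempotent(self, rng):
        traj, _ = self._scene(drift=rng.normal(size=(60, 3)) * 5)
        once = remove_background(traj)
        twice = remove_background(once)
        assert np.max(np.abs(twice.xyz - once.xyz)) < 1e-12

    def test_no_reference_rejected(self):
        traj, _ = self._scene()
        keys = traj.select_role("key")
        with pytest.raises(ValueError):
            remove_background(keys)


class TestRemoveOutliers:
    def test_large_spike_removed(self):
        z = np.full(200, 50.0)
        z[100] = 60.0  # +10 mm > max(5, sd~0)
        out = remove_outliers(_traj(z))
        assert not out.valid[100, 0]
        assert out.valid.sum() == 199

    def test_small_bump_kept_by_5mm_floor(self):
        z = np.full(200, 50.0)
        z[100] = 53.0  # 3 mm <= 5 mm floor
        out = remove_outliers(_traj(z))
        assert out.valid.all()

    def test_window_matches_reported_duration_at_60fps(self):
        # 50 time steps at 60 fps is the 0.83 s baseline window
        assert round(50 / 60.0, 2) == 0.83


class TestSmoothAndFill:
    def test_constant_signal_unchanged(self):
        z = np.full(300, 7.5)
        out = smooth_and_fill(_traj(z))
        assert np.array_equal(out.xyz[:, 0, 2], z)

    def test_long_gap_stays_invalid(self):
        z = np.arange(400.0)
        valid = np.ones(400, bool)
        valid[100:250] = False  # 150-frame gap
        out = smooth_and_fill(_traj(z, valid=valid))
        assert not out.valid[100:250, 0].any()
        assert out.valid[:100, 0].all() and out.valid[250:, 0].all()

    def test_cubic_signal_gap_filled_exactly(self):
        t = np.arange(300.0)
        z = 1e-4 * t**3 - 0.02 * t**2 + 0.3 * t + 5
        valid = np.ones(300, bool)
        valid[140:150] = False  # 10-frame gap
        out = smooth_and_fill(_traj(z, valid=valid), ma_window=1)
        assert out.valid.all()
        assert np.max(np.abs(out.xyz[140:150, 0, 2] - z[140:150])) < 1e-9

    def test_edge_gap_not_extrapolated(self):
        z = np.arange(100.0)
        valid = np.ones(100, bool)
        valid[:10] = False
        out = smooth_and_fill(_traj(z, valid=valid))
        assert not out.valid[:10, 0].any()


def test_chain_is_identity_on_static_noise_free_scene():
    """A static scene passes the whole chain unchanged (up to the depth
    quantization of the renderer)."""
    info = pd.DataFrame(
        {
            "point_id": ["k0", "k1", "k2", "k3", "r0", "r1", "r2"],
            "role": ["key"] * 4 + ["reference"] * 3,
            "arm": ["L1"] * 4 + ["none"] * 3,
        }
    )
    xyz = np.zeros((150, 7, 3))
    for j, pos in enumerate(
        [(0, 0, 100), (20, 5, 110), (40, 12, 105), (60, 20, 95),
         (90, -20, 100), (-30, 40, 100), (90, 45, 100)]
    ):
        xyz[:, j] = pos
    traj = TrajectorySet(info, xyz, np.ones((150, 7), bool), 60.0)
    # cleaned coordinates live in the image frame: fix the origin so the
    # expected positions are known
    stack, tracks = render_depth_stack(
        traj, 0.5, image_shape=(200, 300), origin_mm=(-40.0, -30.0), seed=0
    )
    out = preprocess_tracks(tracks, stack)
    order = [out.point_index(p) for p in info["point_id"]]
    expected = xyz + np.array([40.0, 30.0, 0.0])
    assert out.valid.all()
    assert np.max(np.abs(out.xyz[:, order] - expected)) < 0.02


def test_chain_recovers_drifted_scene(short_stride):
    """Synthetic drift with zero noise leaves reference points stationary
    after background removal."""
    from octokin.synth import smooth_drift

    cfg, traj, _ = short_stride
    drift = smooth_drift(traj.n_frames, 4.0, cfg.fps, seed=3)
    observed, clean = add_observation_noise(traj, 0.0, drift, seed=0)
    out = remove_background(observed)
    refs = out.select_role("reference")
    motion = refs.xyz - refs.xyz[:1]
    assert np.max(np.abs(motion)) < 1e-9
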