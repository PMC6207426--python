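"""Encoding model: projection, speed, compressed KDE, rate-function identities."""

import numpy as np
import pandas as pd
import pytest
from replaydetect import encoding
from replaydetect.encoding import (
    CompressedDensity,
    build_encoding_model,
    clean_and_project_positions,
    compress_insert,
    compute_speed,
    occupancy_zero_handling,
)


class TestGrid:
    def test_layout(self, maze, grid):
        assert grid.bins_per_arm == 41  # floor(90 / 2.15)
        assert grid.n_bins == 123
        assert np.allclose(grid.centers[:2], [0.5 * 2.15, 1.5 * 2.15])
        assert list(np.unique(grid.arm_ids)) == [0, 1, 2]
        # bins ordered arm-by-arm then by distance
        assert np.all(np.diff(grid.arm_ids) >= 0)

    def test_cross_arm_kernel_underflows(self, grid):
        gc = grid.gapped_centers
        d = gc[41] - gc[40]  # adjacent bins across the arm-0/arm-1 boundary
        assert np.exp(-0.5 * (d / 8.0) ** 2) == 0.0


class TestProjection:
    def test_point_on_arm1_center_line(self, maze):
        ang = maze.arm_angles[1]
        raw = pd.DataFrame(
            {"t": [0.0, 0.04], "x": [45 * np.cos(ang)] * 2, "y": [45 * np.sin(ang)] * 2}
        )
        out = clean_and_project_positions(raw, maze)
        assert (out["arm"] == 1).all()
        assert np.allclose(out["lin_pos"], 45.0)

    def test_single_missing_sample_interpolated(self, maze):
        raw = pd.DataFrame(
            {"t": [0.0, 0.04, 0.08], "x": [40.0, np.nan, 42.0], "y": [0.0, np.nan, 0.0]}
        )
        out = clean_and_project_positions(raw, maze, max_gap=0.5)
        assert len(out) == 3
        assert np.isclose(out["lin_pos"].iloc[1], 41.0)

    def test_long_gap_dropped_with_warning(self, maze):
        t = np.arange(10) * 0.04
        x = np.linspace(10, 50, 10)
        x[3:8] = np.nan
        raw = pd.DataFrame({"t": t, "x": x, "y": np.zeros(10)})
        with pytest.warns(UserWarning, match="dropping"):
            out = clean_and_project_positions(raw, maze, max_gap=0.1)
        assert len(out) == 5

    def test_jittered_points_assigned_to_nearest_arm(self, maze):
        """Nearest-segment oracle: brute-force distances to every arm."""
        rng = np.random.default_rng(0)
        arm = rng.integers(0, 3, size=200)
        lin = rng.uniform(5, 85, size=200)
        ang = np.asarray(maze.arm_angles)[arm]
        x = lin * np.cos(ang) + rng.normal(0, 1.5, 200)
        y = lin * np.sin(ang) + rng.normal(0, 1.5, 200)
        out = clean_and_project_positions(pd.DataFrame({"t": np.arange(200) * 0.04, "x": x, "y": y}), maze)
        # oracle: per point, distance to each arm segment
        expected = []
        for xi, yi in zip(x, y):
            dists = []
            for a in range(3):
                u = np.array([np.cos(maze.arm_angles[a]), np.sin(maze.arm_angles[a])])
                s = np.clip(xi * u[0] + yi * u[1], 0, maze.arm_length)
                dists.append(np.hypot(xi - s * u[0], yi - s * u[1]))
            expected.append(int(np.argmin(dists)))
        assert np.array_equal(out["arm"].to_numpy(), expected)

    def test_off_maze_points_removed(self, maze):
        raw = pd.DataFrame(
            {"t": [0.0, 0.04, 0.08], "x": [10.0, 60.0, 12.0], "y": [0.0, 60.0, 0.0]}
        )
        out = clean_and_project_positions(raw, maze, max_gap=1.0)
        assert len(out) == 3  # interpolated back through the gap
        assert out["lin_pos"].iloc[1] == pytest.approx(11.0)


class TestSpeed:
    def test_constant_position_zero_speed(self):
        pos = pd.DataFrame({"t": np.arange(50) * 0.02, "arm": 0, "lin_pos": 30.0})
        out = compute_speed(pos)
        assert np.allclose(out["speed"], 0.0)

    def test_linear_motion_recovered(self):
        t = np.arange(200) * 0.02
        pos = pd.DataFrame({"t": t, "arm": 0, "lin_pos": 30.0 * t})
        out = compute_speed(pos)
        interior = out["speed"].to_numpy()[40:-40]
        assert np.all(np.abs(interior - 30.0) < 0.5)

    def test_no_cross_arm_gradient(self):
        """An arm switch must not create a spurious velocity spike."""
        t = np.arange(100) * 0.02
        arm = np.where(t < 1.0, 0, 1)
        pos = pd.DataFrame({"t": t, "arm": arm, "lin_pos": np.full(100, 2.0)})
        out = compute_speed(pos)
        assert np.allclose(out["speed"], 0.0)

    def test_too_few_samples(self):
        pos = pd.DataFrame({"t": [0.0, 0.02], "arm": [0, 0], "lin_pos": [0.0, 1.0]})
        with pytest.raises(ValueError):
            compute_speed(pos)


class TestCompressedDensity:
    def test_threshold_zero_keeps_every_sample(self):
        d = CompressedDensity(np.array([8.0]), 0.0)
        d.insert_many(np.linspace(0, 1, 50)[:, None])
        assert d.n_components == 50
        assert d.total_weight == 50

    def test_identical_samples_merge(self):
        d = CompressedDensity(np.array([8.0]), 1.0)
        compress_insert(d, [42.0], 1.0)
        compress_insert(d, [42.0], 1.0)
        assert d.n_components == 1
        assert d.weights[0] == 2.0
        assert d.means[0, 0] == 42.0

    def test_non_finite_sample_rejected(self):
        d = CompressedDensity(np.array([8.0]), 1.0)
        with pytest.raises(ValueError):
            d.insert([np.nan])

    def test_merge_updates_weighted_mean(self):
        d = CompressedDensity(np.array([10.0]), 1.0)
        d.insert([0.0])
        d.insert([3.0])  # normalized distance 0.3 < 1 -> merge
        assert d.n_components == 1
        assert d.means[0, 0] == pytest.approx(1.5)
        d.insert([3.0])  # weight-2 component at 1.5; new mean (2*1.5+3)/3
        assert d.means[0, 0] == pytest.approx(2.0)
        assert d.total_weight == 3

    @pytest.mark.parametrize("threshold,bound", [(0.5, 0.01), (1.0, 0.05)])
    def test_compression_fidelity_against_full_kde(self, threshold, bound):
        """Moment-free merging perturbs the density by O(threshold^2) of peak."""
        rng = np.random.default_rng(1)
        samples = rng.uniform(0, 90, size=(1000, 1))
        grid_pts = ((np.arange(41) + 0.5) * 2.15)[:, None]
        d = CompressedDensity(np.array([8.0]), threshold)
        d.insert_many(samples)
        # independent dense KDE
        z = (grid_pts[:, 0][:, None] - samples[:, 0][None, :]) / 8.0
        full = np.exp(-0.5 * z**2).sum(axis=1) / (len(samples) * 8.0 * np.sqrt(2 * np.pi))
        est = d.evaluate(grid_pts)
        assert d.n_components < len(samples)
        assert np.abs(est - full).max() / full.max() < bound

    def test_total_weight_equals_insert_count_property(self):
        rng = np.random.default_rng(3)
        d = CompressedDensity(np.array([8.0, 30.0]), 1.5)
        n = 200
        for s in rng.normal(0, 20, size=(n, 2)):
            d.insert(s)
        assert d.total_weight == n
        assert np.all(d.weights >= 1)


def _sweep_session(maze, grid):
    """Deterministic slow sweep of all arms with one marked spike train."""
    dt = 0.02
    frames = []
    t0 = 0.0
    for arm in range(3):
        n = 500
        t = t0 + dt * np.arange(n)
        lin = np.linspace(0.5, 89.5, n)
        frames.append(pd.DataFrame({"t": t, "arm": arm, "lin_pos": lin, "speed": 10.0}))
        t0 = t[-1] + dt
    pos = pd.concat(frames, ignore_index=True)
    return pos


class TestBuildModel:
    def test_stationary_animal_raises(self, grid, maze):
        pos = pd.DataFrame({"t": np.arange(100) * 0.02, "arm": 0, "lin_pos": 30.0, "speed": 0.0})
        spikes = pd.DataFrame(
            {"tetrode_id": [0], "t": [0.5], "a1": [100.0], "a2": [100.0], "a3": [100.0], "a4": [100.0]}
        )
        with pytest.raises(ValueError, match="speed threshold"):
            build_encoding_model(spikes, pos, grid)

    def test_tetrode_without_spikes_raises(self, grid, maze):
        pos = _sweep_session(maze, grid)
        spikes = pd.DataFrame(
            {"tetrode_id": [0], "t": [5.0], "a1": [100.0], "a2": [100.0], "a3": [100.0], "a4": [100.0]}
        )
        with pytest.raises(ValueError, match="zero qualifying"):
            build_encoding_model(spikes, pos, grid, tetrodes=[0, 1])

    def test_single_spike_gives_gaussian_bump(self, grid, maze):
        pos = _sweep_session(maze, grid)
        # spike when the animal is at ~45 cm on arm 0
        idx = (pos["arm"] == 0) & (np.abs(pos["lin_pos"] - 45.0) < 0.1)
        t_spk = float(pos.loc[idx, "t"].iloc[0])
        spikes = pd.DataFrame(
            {"tetrode_id": [0], "t": [t_spk], "a1": [150.0], "a2": [150.0], "a3": [150.0], "a4": [150.0]}
        )
        model = build_encoding_model(spikes, pos, grid, compression_threshold=1.0)
        px = model.tetrode_models[0].px
        peak = int(px.argmax())
        assert grid.arm_ids[peak] == 0
        assert abs(grid.centers[peak] - 45.0) <= grid.spacing
        assert np.all(px[41:] < 1e-12)  # no leakage into other arms

    def test_rate_occupancy_identity(self, small_model, grid):
        """sum_x lambda(x) pi(x) dx = mu for every tetrode (1% tolerance)."""
        for m in small_model.tetrode_models.values():
            integral = float(np.sum(m.lam_x * m.pi) * grid.spacing)
            assert integral == pytest.approx(m.mu, rel=0.01)

    def test_rebuild_deterministic(self, small_run, grid):
        pos, spikes = small_run
        a = build_encoding_model(spikes, pos, grid, compression_threshold=1.8)
        b = build_encoding_model(spikes, pos, grid, compression_threshold=1.8)
        for k in a.tetrode_models:
            assert np.array_equal(a.tetrode_models[k].joint.means, b.tetrode_models[k].joint.means)
            assert np.array_equal(a.tetrode_models[k].px, b.tetrode_models[k].px)

    def test_model_round_trip(self, small_model, tmp_path, grid):
        path = tmp_path / "model.npz"
        encoding.save_model(small_model, path)
        back = encoding.load_model(path)
        assert back.tetrode_ids == small_model.tetrode_ids
        for k in small_model.tetrode_models:
            assert np.allclose(back.tetrode_models[k].lam_x, small_model.tetrode_models[k].lam_x)


class TestOccupancyMask:
    def test_fully_visited_no_mask(self, small_model):
        for m in small_model.tetrode_models.values():
            assert not m.mask.any()

    def test_unvisited_arm_masked(self, grid, maze):
        # animal only ever on arm 0
        n = 800
        pos = pd.DataFrame(
            {"t": np.arange(n) * 0.02, "arm": 0,
             "lin_pos": np.tile(np.linspace(1, 89, 400), 2), "speed": 10.0}
        )
        rng = np.random.default_rng(0)
        ts = np.sort(rng.uniform(0, pos["t"].iloc[-1], 60))
        spikes = pd.DataFrame(
            {"tetrode_id": 0, "t": ts, "a1": 120.0, "a2": 110.0, "a3": 100.0, "a4": 90.0}
        )
        model = build_encoding_model(spikes, pos, grid, compression_threshold=1.0)
        m = occupancy_zero_handling(model.tetrode_models[0], epsilon=1e-3)
        assert not m.mask[grid.arm_slice(0)].any()
        assert m.mask[grid.arm_slice(1)].all() and m.mask[grid.arm_slice(2)].all()
        # masked rates floored, not zero/inf
        assert np.all(np.isfinite(m.lam_x)) and np.all(m.lam_x > 0)


def test_map_arm_stable_under_strong_compression(maze, grid):
    """Compression at threshold 2 rarely flips the MAP arm of informative posteriors."""
    from replaydetect import decoding, synthetic

    cells = synthetic.make_default_population(maze, 10, 3, seed=0)
    pos, rspk = synthetic.simulate_run_epoch(maze, cells, 90.0, seed=1)
    pos = encoding.compute_speed(pos)
    bspk, _ = synthetic.simulate_burst_epoch(maze, cells, 120.0, seed=2, t0=100.0)
    m0 = build_encoding_model(rspk, pos, grid, compression_threshold=0.0)
    m2 = build_encoding_model(rspk, pos, grid, compression_threshold=2.0)
    s0 = decoding.decode_stream(m0, bspk, 0.010, 100.0, 220.0)
    s2 = decoding.decode_stream(m2, bspk, 0.010, 100.0, 220.0)
    map_prob = s0.posterior[np.arange(s0.n_bins), s0.map_index]
    sel = (s0.mua_counts >= 3) & (map_prob > 0.05)  # candidate-burst, informative bins
    assert sel.sum() > 50
    assert (s0.map_arm[sel] != s2.map_arm[sel]).mean() < 0.1
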