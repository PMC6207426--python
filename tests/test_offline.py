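"""Offline reference pipeline: MUA, detrending, bursts, content scores."""

import numpy as np
import pandas as pd
import pytest

from replaydetect import offline
from replaydetect.offline import (
    ContentMeasures,
    MuaSignal,
    bias_max_score,
    bias_measures,
    classify_events,
    compute_mua,
    detect_bursts,
    detrend_and_zscore,
    line_fit_score,
    shuffle_posteriors,
    sequence_score,
    trajectory_abs_correlation,
    BurstInterval,
)


def _spike_frame(times):
    t = np.asarray(times, float)
    return pd.DataFrame(
        {"tetrode_id": np.zeros(len(t), int), "t": t,
         "a1": 100.0, "a2": 100.0, "a3": 100.0, "a4": 100.0}
    )


class TestMua:
    def test_no_spikes_zero_rate(self):
        mua = compute_mua(_spike_frame([]), (0.0, 1.0))
        assert np.all(mua.rate == 0)
        assert len(mua.t) == 1000

    def test_single_spike_kernel_mass(self):
        mua = compute_mua(_spike_frame([0.5]), (0.0, 1.0))
        assert mua.rate.sum() * 0.001 == pytest.approx(1.0, abs=1e-9)
        assert abs(mua.t[mua.rate.argmax()] - 0.5) < 0.002

    def test_total_integral_equals_spike_count(self):
        rng = np.random.default_rng(0)
        times = rng.uniform(0.2, 9.8, 500)
        mua = compute_mua(_spike_frame(times), (0.0, 10.0))
        assert mua.rate.sum() * 0.001 == pytest.approx(500, abs=0.01)


class TestDetrend:
    def test_white_noise_trend_is_flat(self):
        rng = np.random.default_rng(1)
        x = 50.0 + rng.normal(0, 5, 60_000)
        mua = MuaSignal(t=0.001 * np.arange(len(x)), rate=x)
        out = detrend_and_zscore(mua)
        assert np.abs(out.trend - 50.0).max() < 5.0
        # z is essentially the standardized input noise
        r = np.corrcoef(out.z, (x - x.mean()) / x.std())[0, 1]
        assert r > 0.99
        assert abs(out.z.mean()) < 1e-9 and out.z.std() == pytest.approx(1.0)

    def test_slow_sinusoid_removed(self):
        """A 60 s oscillation loses > 90% of its power; fast bursts survive."""
        t = 0.001 * np.arange(120_000)
        slow = 20.0 * np.sin(2 * np.pi * t / 60.0)
        bursts = np.zeros_like(t)
        for onset in np.arange(3.0, 118.0, 5.0):
            sel = (t >= onset) & (t < onset + 0.08)
            bursts[sel] = 300.0
        x = 100.0 + slow + bursts
        out = detrend_and_zscore(MuaSignal(t=t, rate=x))
        detrended = out.rate - out.trend

        def slow_power(sig):
            c = np.cos(2 * np.pi * t / 60.0)
            s = np.sin(2 * np.pi * t / 60.0)
            return (sig @ c) ** 2 + (sig @ s) ** 2

        assert slow_power(detrended) < 0.1 * slow_power(x - x.mean())
        # bursts preserved: detrended peak close to original burst height
        assert detrended.max() > 250.0

    def test_time_reversal_symmetry(self):
        rng = np.random.default_rng(2)
        x = 10 + rng.random(30_000) * np.linspace(1, 4, 30_000)
        t = 0.001 * np.arange(len(x))
        fwd = detrend_and_zscore(MuaSignal(t=t, rate=x))
        rev = detrend_and_zscore(MuaSignal(t=t, rate=x[::-1]))
        assert np.allclose(rev.trend, fwd.trend[::-1], rtol=1e-10, atol=1e-10)

    def test_constant_signal_raises(self):
        x = np.full(20_000, 3.0)
        with pytest.raises(ValueError, match="constant"):
            detrend_and_zscore(MuaSignal(t=0.001 * np.arange(len(x)), rate=x))


class TestBursts:
    def _sig(self, z):
        z = np.asarray(z, float)
        return MuaSignal(t=0.001 * (np.arange(len(z)) + 0.5), rate=z, z=z)

    def test_flat_signal_no_bursts(self):
        assert detect_bursts(self._sig(np.zeros(1000))) == []

    def test_single_pulse_bounds_at_entry_crossings(self):
        z = np.zeros(1000)
        z[100:200] = 3.0  # supra-enter from sample 100 to 199
        out = detect_bursts(self._sig(z))
        assert len(out) == 1
        assert out[0].onset == pytest.approx(0.100)
        assert out[0].offset == pytest.approx(0.200)
        assert out[0].peak_z == 3.0

    def test_low_peak_discarded(self):
        z = np.zeros(1000)
        z[100:200] = 1.0  # above enter, below peak_min
        assert detect_bursts(self._sig(z)) == []

    def test_merge_below_20ms_gap(self):
        z = np.zeros(1000)
        z[100:150] = 2.6
        z[165:215] = 0.8  # 15 ms gap -> merged; peak of merged interval 2.6
        out = detect_bursts(self._sig(z))
        assert len(out) == 1
        assert out[0].onset == pytest.approx(0.100)
        assert out[0].offset == pytest.approx(0.215)

    def test_gap_above_20ms_not_merged(self):
        z = np.zeros(1000)
        z[100:150] = 2.6
        z[175:225] = 2.6  # 25 ms gap
        assert len(detect_bursts(self._sig(z))) == 2

    def test_matches_threshold_crossing_oracle(self):
        """Brute-force scan over every sample agrees on random signals."""
        rng = np.random.default_rng(3)
        z = rng.normal(0, 1.2, 5000)
        out = detect_bursts(self._sig(z), merge_gap=0.0)
        # oracle: maximal runs above 0.5 with max >= 2.5
        runs = []
        i = 0
        while i < len(z):
            if z[i] > 0.5:
                j = i
                while j < len(z) and z[j] > 0.5:
                    j += 1
                if z[i:j].max() >= 2.5:
                    runs.append((i, j))
                i = j
            else:
                i += 1
        assert len(out) == len(runs)
        for b, (i, j) in zip(out, runs):
            assert b.onset == pytest.approx(0.001 * i)
            assert b.offset == pytest.approx(0.001 * j)


class TestBias:
    def test_uniform_posteriors(self, grid):
        P = np.full((5, grid.n_bins), 1.0 / grid.n_bins)
        bias, bm = bias_measures(P, grid)
        assert np.allclose(bias, 1 / 3)
        assert bm == pytest.approx(0.0)

    def test_all_mass_one_arm(self, grid):
        P = np.zeros((4, grid.n_bins))
        P[:, 10] = 1.0
        _, bm = bias_measures(P, grid)
        assert bm == pytest.approx(1.0)

    def test_half_and_half(self, grid):
        P = np.zeros((6, grid.n_bins))
        P[:3, 10] = 1.0  # arm 0
        P[3:, grid.bins_per_arm + 10] = 1.0  # arm 1
        bias, bm = bias_measures(P, grid)
        assert np.allclose(bias, [0.5, 0.5, 0.0])
        assert bm == pytest.approx(0.25)


class TestShuffles:
    def test_mass_conserved_every_shuffle(self, grid):
        rng = np.random.default_rng(4)
        P = rng.random((8, grid.n_bins))
        P /= P.sum(axis=1, keepdims=True)
        for S in shuffle_posteriors(P, n=20, seed=1):
            assert np.allclose(np.sort(S, axis=1), np.sort(P, axis=1))
            assert np.allclose(S.sum(axis=1), 1.0)

    def test_uniform_posterior_degenerate_score_zero(self, grid):
        P = np.full((6, grid.n_bins), 1.0 / grid.n_bins)
        with pytest.warns(UserWarning, match="degenerate"):
            assert bias_max_score(P, grid, n_shuffles=50, seed=0) == 0.0

    def test_strong_single_arm_event_scores_high(self, grid):
        rng = np.random.default_rng(5)
        P = np.zeros((8, grid.n_bins))
        P[np.arange(8), rng.integers(5, 35, 8)] = 1.0  # concentrated, arm 0
        assert bias_max_score(P, grid, n_shuffles=500, seed=1) > 3.0

    def test_null_self_consistency(self, grid):
        """Scoring an already-shuffled event gives z near 0 in expectation."""
        rng = np.random.default_rng(6)
        P = np.zeros((8, grid.n_bins))
        P[np.arange(8), rng.integers(5, 35, 8)] = 1.0
        S = next(shuffle_posteriors(P, n=1, seed=99))
        z = bias_max_score(S, grid, n_shuffles=300, seed=2)
        assert abs(z) < 3.0


class TestLineFit:
    def test_one_hot_on_line_scores_one(self, grid):
        sl = grid.arm_slice(0)
        centers = grid.centers[sl]
        P = np.zeros((6, len(centers)))
        P[np.arange(6), 10] = 1.0  # zero-velocity line
        assert line_fit_score(P, centers) == pytest.approx(1.0)

    def test_uniform_band_fraction(self, grid):
        """Uniform in-arm posterior: best line captures the widest band."""
        sl = grid.arm_slice(0)
        centers = grid.centers[sl]
        P = np.full((5, len(centers)), 1.0 / len(centers))
        # a 30 cm band over a 90 cm arm captures about a third of the mass;
        # slightly tilted lines can slip between bin centers and cover 14
        # bins (30/2.15 = 13.95) in some time bins, never 15
        score = line_fit_score(P, centers)
        assert 13 / 41 <= score <= 14 / 41
        assert score == pytest.approx(30 / 90, abs=0.01)

    def test_single_bin_raises(self, grid):
        sl = grid.arm_slice(0)
        with pytest.raises(ValueError):
            line_fit_score(np.ones((1, 41)) / 41, grid.centers[sl])

    def test_matches_brute_force_line_search(self, grid):
        """Independent double-loop search over the same line grid."""
        rng = np.random.default_rng(7)
        sl = grid.arm_slice(1)
        centers = grid.centers[sl]
        P = rng.random((7, len(centers)))
        P /= P.sum(axis=1, keepdims=True)
        got = line_fit_score(P, centers)
        best = 0.0
        for c in centers:
            for v in np.arange(-1500.0, 1500.0 + 1e-9, 75.0):
                scores = []
                for b in range(7):
                    p = c + v * 0.010 * b
                    scores.append(P[b, np.abs(centers - p) <= 15.0].sum())
                best = max(best, np.mean(scores))
        assert got == pytest.approx(best, abs=1e-12)


class TestTrajectoryCorrelation:
    def test_deterministic_ramp_gives_one(self, grid):
        centers = grid.centers[grid.arm_slice(0)]
        P = np.zeros((8, len(centers)))
        P[np.arange(8), 4 + 3 * np.arange(8)] = 1.0
        assert trajectory_abs_correlation(P, centers, n_traj=50, seed=0) == pytest.approx(1.0)

    def test_constant_position_degenerate(self, grid):
        centers = grid.centers[grid.arm_slice(0)]
        P = np.zeros((5, len(centers)))
        P[:, 7] = 1.0
        with pytest.raises(ValueError, match="degenerate"):
            trajectory_abs_correlation(P, centers, n_traj=20, seed=0)

    def test_structureless_posterior_near_independence_null(self, grid):
        centers = grid.centers[grid.arm_slice(0)]
        B = 10
        P = np.full((B, len(centers)), 1.0 / len(centers))
        got = trajectory_abs_correlation(P, centers, n_traj=2000, seed=1)
        # Monte-Carlo null: |r| of B iid uniforms against time
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 90, size=(2000, B))
        t = np.arange(B) - (B - 1) / 2
        Xc = X - X.mean(axis=1, keepdims=True)
        r = (Xc @ t) / np.sqrt((t**2).sum() * (Xc**2).sum(axis=1))
        expected = np.abs(r).mean()
        assert got == pytest.approx(expected, abs=0.05)

    def test_pooled_mode(self, grid):
        centers = grid.centers[grid.arm_slice(0)]
        P = np.zeros((8, len(centers)))
        P[np.arange(8), 4 + 3 * np.arange(8)] = 1.0
        got = trajectory_abs_correlation(P, centers, n_traj=50, seed=0, mode="pooled")
        assert got == pytest.approx(1.0)


class TestSequenceScore:
    def test_steep_sweep_scores_high(self, grid):
        P = np.zeros((10, grid.n_bins))
        P[np.arange(10), 3 * np.arange(10) + 5] = 1.0  # ramp on arm 0
        z = sequence_score(P, grid, n_shuffles=200, n_traj=200, n_traj_null=50, seed=3)
        assert z > 2.0

    def test_shuffled_event_scores_near_zero(self, grid):
        P = np.zeros((10, grid.n_bins))
        P[np.arange(10), 3 * np.arange(10) + 5] = 1.0
        S = next(shuffle_posteriors(P, n=1, seed=11))
        z = sequence_score(S, grid, n_shuffles=200, n_traj=200, n_traj_null=50, seed=4)
        assert abs(z) < 3.0


class TestClassification:
    def test_threshold_logic(self):
        m = ContentMeasures(bias=np.array([1.0, 0, 0]), bias_max=0.9,
                            bias_max_score=4.0, arm=0, line_fit_score=0.2)
        assert m.is_replay()
        m.bias_max_score = 2.9
        m.line_fit_score = 0.5
        assert not m.is_replay()
        m.bias_max_score = 4.0
        m.line_fit_score = 0.1  # strictly-greater rule
        assert not m.is_replay()

    def test_joint_event_split_with_both_halves_replaying(self, grid):
        """A 140 ms arm0->arm1 sweep splits with two replay halves."""
        bpa = grid.bins_per_arm
        idx = np.concatenate([35 - 4 * np.arange(7), bpa + 5 + 4 * np.arange(7)])
        P = np.zeros((14, grid.n_bins))
        P[np.arange(14), idx] = 1.0
        burst = BurstInterval(onset=10.0, offset=10.14, peak_z=3.0)
        events = classify_events([burst], [P], grid, n_shuffles=300, seed=0)
        assert len(events) == 1
        e = events[0]
        assert e.structure == "split" and e.duration_class == "long"
        assert [s.replay for s in e.subevents] == [True, True]
        assert [s.arm for s in e.subevents] == [0, 1]
        assert e.subevents[0].interval == (10.0, pytest.approx(10.07))

    def test_short_burst_correlation_skipped(self, grid):
        P = np.zeros((2, grid.n_bins))
        P[:, 5] = 1.0
        burst = BurstInterval(onset=0.0, offset=0.02, peak_z=3.0)
        events = classify_events([burst], [P], grid, n_shuffles=100, seed=0,
                                 with_sequence_scores=True)
        assert events[0].subevents[0].measures.corr_skipped
        assert events[0].structure == "whole"

    def test_reference_table_round_trip(self, grid):
        P = np.zeros((8, grid.n_bins))
        P[np.arange(8), 5 + 3 * np.arange(8)] = 1.0
        burst = BurstInterval(onset=1.0, offset=1.08, peak_z=4.2)
        events = classify_events([burst], [P], grid, n_shuffles=100, seed=0)
        df = offline.reference_to_frame(events)
        back = offline.reference_from_frame(df)
        assert len(back) == len(events)
        assert back[0].structure == events[0].structure
        assert back[0].subevents[0].replay == events[0].subevents[0].replay
        assert back[0].interval.onset == events[0].interval.onset
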