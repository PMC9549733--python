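import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motilitylab.features import (
    FeatureParams,
    displacement_autocorr,
    feature_table,
    hurst_rs,
    linearity_metrics,
    movement_occupancy,
    msd_profile,
    nongauss_alpha2,
    path_metrics,
    random_walk_deltas,
    track_features,
    trackmate_summary,
)
from motilitylab.io import TrackSet
from motilitylab.simulate import SimulationConfig, simulate_tracks

from conftest import make_track

TOL = 1e-9


class TestPathMetrics:
    def test_straight_line(self):
        t = make_track([(0, 0), (1, 0), (2, 0), (3, 0), (4, 0)])
        m = path_metrics(t)
        assert m["total_distance"] == pytest.approx(4, abs=TOL)
        assert m["net_distance"] == pytest.approx(4, abs=TOL)
        assert m["progressivity"] == pytest.approx(1, abs=TOL)
        assert m["avg_speed"] == pytest.approx(1, abs=TOL)

    def test_closed_loop(self, loop_track):
        m = path_metrics(loop_track)
        assert m["total_distance"] == pytest.approx(4, abs=TOL)
        assert m["net_distance"] == pytest.approx(0, abs=TOL)
        assert m["progressivity"] == pytest.approx(0, abs=TOL)

    def test_zigzag_hand_arithmetic(self, zigzag_track):
        m = path_metrics(zigzag_track)
        assert m["total_distance"] == pytest.approx(3 * np.sqrt(2), abs=TOL)
        assert m["net_distance"] == pytest.approx(np.sqrt(10), abs=TOL)
        assert m["progressivity"] == pytest.approx(np.sqrt(10) / (3 * np.sqrt(2)), abs=TOL)

    def test_stationary_progressivity_zero(self, stationary_track):
        assert path_metrics(stationary_track)["progressivity"] == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 60))
    def test_total_at_least_net(self, seed, n):
        rng = np.random.default_rng(seed)
        m = path_metrics(make_track(rng.normal(size=(n, 2), scale=3.0)))
        assert m["total_distance"] >= m["net_distance"] - 1e-12
        assert m["min_speed"] <= m["avg_speed"] <= m["max_speed"]


class TestLinearity:
    def test_perfect_line(self):
        x = np.arange(6, dtype=float)
        t = make_track(np.column_stack([x, 2 * x + 1]))
        m = linearity_metrics(t)
        assert m["linearity"] == pytest.approx(1, abs=TOL)
        assert m["spearmanrsq"] == pytest.approx(1, abs=TOL)

    def test_axis_aligned_track_is_degenerate_one(self):
        x = np.arange(6, dtype=float)
        t = make_track(np.column_stack([x, np.full(6, 3.0)]))
        m = linearity_metrics(t)
        assert m["linearity"] == 1.0 and m["spearmanrsq"] == 1.0

    def test_symmetric_parabola_uncorrelated(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        t = make_track(np.column_stack([x, x**2]))
        m = linearity_metrics(t)
        assert m["linearity"] == pytest.approx(0, abs=TOL)
        assert m["spearmanrsq"] == pytest.approx(0, abs=TOL)

    def test_3d_uses_two_largest_variance_axes(self):
        x = np.arange(10, dtype=float)
        pos = np.column_stack([x, 2 * x, 0.001 * np.sin(x)])
        assert linearity_metrics(make_track(pos))["linearity"] == pytest.approx(1, abs=1e-6)


class TestMSD:
    def test_ballistic_slope_exactly_two(self, line_track):
        lags, msd, slope = msd_profile(line_track, 4)
        np.testing.assert_allclose(msd, lags.astype(float) ** 2, atol=TOL)
        assert slope == pytest.approx(2, abs=TOL)

    def test_stationary_undefined(self, stationary_track):
        _, _, slope = msd_profile(stationary_track, 4)
        assert np.isnan(slope)

    def test_brownian_ensemble_slope_near_one(self, brownian_ensemble):
        slopes = [msd_profile(t, 20)[2] for t in brownian_ensemble]
        assert 0.95 <= np.mean(slopes) <= 1.05

    def test_gap_track_rejected(self):
        t = make_track([(0, 0), (1, 0), (5, 0)], frames=[0, 1, 5])
        with pytest.raises(ValueError, match="gap"):
            msd_profile(t, 2)


class TestHurst:
    def test_accelerating_monotone_track_is_persistent(self):
        x = np.arange(256, dtype=float) ** 2
        t = make_track(np.column_stack([x, 0.3 * x]))
        assert hurst_rs(t) >= 0.9

    def test_white_noise_increments_near_half(self):
        cfg = SimulationConfig(model="brownian", n_tracks=40, n_frames=128,
                               sigma=1.0, seed=7)
        ts, _ = simulate_tracks(cfg, "c")
        h = np.mean([hurst_rs(t) for t in ts])
        assert h == pytest.approx(0.5, abs=0.1)

    def test_alternating_steps_antipersistent(self):
        pos = np.zeros((40, 2))
        pos[1::2] = 1.0
        assert hurst_rs(make_track(pos)) < 0.5

    def test_short_track_rejected(self):
        with pytest.raises(ValueError, match="16"):
            hurst_rs(make_track(np.random.default_rng(0).normal(size=(10, 2))))

    def test_constant_increments_undefined(self, line_track):
        assert np.isnan(hurst_rs(make_track(
            np.column_stack([np.arange(32, dtype=float), np.zeros(32)]))))


class TestNonGauss:
    def test_rademacher_steps(self):
        # ±1 steps on both axes: per-axis α₂ = 1/3 − 1 = −2/3
        rng = np.random.default_rng(1)
        steps = rng.choice([-1.0, 1.0], size=(30, 2))
        pos = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
        assert nongauss_alpha2(make_track(pos)) == pytest.approx(-2 / 3, abs=TOL)

    def test_gaussian_ensemble_near_zero(self, brownian_ensemble):
        vals = [nongauss_alpha2(t) for t in brownian_ensemble]
        assert abs(np.mean(vals)) < 0.1

    def test_stationary_undefined(self, stationary_track):
        assert np.isnan(nongauss_alpha2(stationary_track))


class TestRandomWalkDeltas:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(21)
        t = make_track(np.cumsum(rng.normal(size=(30, 2)), axis=0))
        a = random_walk_deltas(t, n_sim=50, seed=9)
        b = random_walk_deltas(t, n_sim=50, seed=9)
        assert a == b

    def test_straight_line_beats_random_walk(self, line_track):
        d = random_walk_deltas(line_track, n_sim=200, seed=9)
        assert d["rw_netdist"] > 0

    def test_brownian_self_consistency(self, brownian_ensemble):
        # Brownian tracks are themselves isotropic walks with their own step
        # lengths, so ensemble-mean deltas vanish
        deltas = [random_walk_deltas(t, n_sim=50, seed=3, subtrack_len=20)
                  for t in brownian_ensemble.tracks[:120]]
        for key, scale in (("rw_linearity", 0.02), ("rw_kurtosis", 0.1)):
            vals = np.array([d[key] for d in deltas])
            assert abs(np.nanmean(vals)) < max(
                3 * np.nanstd(vals) / np.sqrt(len(vals)), scale
            )
        net = np.array([d["rw_netdist"] for d in deltas])
        assert abs(net.mean()) < 3 * net.std(ddof=1) / np.sqrt(len(net))


class TestMovementOccupancy:
    def test_all_moving(self):
        t = make_track(np.column_stack([np.arange(5, dtype=float), np.zeros(5)]))
        m = movement_occupancy(t, (0.5,), subtrack_len=5)
        assert m["time_moving_0p5"] == 1.0
        assert m["avg_moving_speed_0p5"] == pytest.approx(1.0)

    def test_stationary(self, stationary_track):
        m = movement_occupancy(stationary_track, (1.0,), subtrack_len=20)
        assert m["time_moving_1"] == 0.0
        assert m["avg_moving_speed_1"] == 0.0

    def test_half_moving_hand_case(self):
        # step speeds {2, 0, 2, 0} against threshold 1, one sub-track
        pos = np.column_stack([[0.0, 2, 2, 4, 4], np.zeros(5)])
        m = movement_occupancy(make_track(pos), (1.0,), subtrack_len=5)
        assert m["time_moving_1"] == pytest.approx(0.5)
        assert m["avg_moving_speed_1"] == pytest.approx(2.0)

    def test_subtrack_longer_than_track_rejected(self, zigzag_track):
        with pytest.raises(ValueError):
            movement_occupancy(zigzag_track, (1.0,), subtrack_len=10)


class TestAutocorr:
    def test_constant_velocity_fully_correlated(self, line_track):
        m = displacement_autocorr(line_track, (1, 2, 5))
        for lag in (1, 2, 5):
            assert m[f"autocorr_lag{lag}"] == pytest.approx(1.0, abs=TOL)

    def test_alternating_steps_anticorrelated(self):
        pos = np.zeros((30, 2))
        pos[1::2, 0] = 1.0
        m = displacement_autocorr(make_track(pos), (1,))
        assert m["autocorr_lag1"] == pytest.approx(-1.0, abs=TOL)

    def test_white_noise_uncorrelated(self, brownian_ensemble):
        vals = np.array([
            displacement_autocorr(t, (1,))["autocorr_lag1"]
            for t in brownian_ensemble
        ])
        assert abs(vals.mean()) < 3 * vals.std(ddof=1) / np.sqrt(len(vals))

    def test_lag_too_large(self, zigzag_track):
        with pytest.raises(ValueError, match="lag"):
            displacement_autocorr(zigzag_track, (5,))


class TestTrackmateSummary:
    def test_straight_line(self):
        t = make_track(np.column_stack([np.arange(5, dtype=float), np.zeros(5)]))
        m = trackmate_summary(t)
        assert m["tm_total_displacement"] == pytest.approx(4.0, abs=TOL)
        assert m["tm_mean_straight_line_speed"] == pytest.approx(1.0, abs=TOL)
        assert m["tm_velocity"] == pytest.approx(1.0, abs=TOL)

    def test_closed_loop(self, loop_track):
        m = trackmate_summary(loop_track)
        assert m["tm_total_displacement"] == pytest.approx(0, abs=TOL)
        assert m["tm_mean_straight_line_speed"] == pytest.approx(0, abs=TOL)
        assert m["tm_velocity"] > 0

    def test_zigzag_at_ten_minutes(self, zigzag_track):
        m = trackmate_summary(zigzag_track)
        assert m["tm_mean_straight_line_speed"] == pytest.approx(
            np.sqrt(10) / 30, abs=TOL
        )


class TestInvariances:
    def _features(self, t):
        return track_features(t, FeatureParams(rw_n_sim=20))

    def test_translation_invariance(self):
        rng = np.random.default_rng(12)
        pos = np.cumsum(rng.normal(size=(40, 2)), axis=0)
        a = self._features(make_track(pos))
        b = self._features(make_track(pos + np.array([123.4, -56.7])))
        for k in a:
            np.testing.assert_allclose(a[k], b[k], atol=1e-8, err_msg=k)

    def test_rotation_invariance_of_geometry_features(self):
        rng = np.random.default_rng(13)
        pos = np.cumsum(rng.normal(size=(64, 2)), axis=0)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        a = track_features(make_track(pos), FeatureParams(rw_n_sim=1))
        b = track_features(make_track(pos @ R.T), FeatureParams(rw_n_sim=1))
        # per-axis statistics (hurst_rs, nongauss, linearity) are rotation-
        # invariant only in distribution, not per sample — excluded here
        for k in ("total_distance", "net_distance", "progressivity", "avg_speed",
                  "msd_slope", "autocorr_lag1", "tm_velocity"):
            np.testing.assert_allclose(a[k], b[k], atol=1e-8, err_msg=k)
        # linearity is axis-dependent by construction: rotation changes it
        assert abs(a["linearity"] - b["linearity"]) > 1e-6


class TestFeatureTable:
    def test_one_row_per_track_and_missing_policy(self, brownian_ensemble):
        ts = TrackSet(
            brownian_ensemble.tracks[:3]
            + [make_track(np.zeros((72, 2)), track_id="frozen",
                          frame_interval=brownian_ensemble.frame_interval)],
            brownian_ensemble.frame_interval,
        )
        fm = feature_table(ts, FeatureParams(rw_n_sim=10))
        assert len(fm) == 4
        row = fm.loc["frozen"]
        assert np.isnan(row["msd_slope"]) and np.isnan(row["hurst_rs"]) \
            and np.isnan(row["nongauss"])
        assert row["total_distance"] == 0.0
        assert fm.attrs["n_missing"]["msd_slope"] == 1

    def test_deterministic(self, brownian_ensemble):
        ts = TrackSet(brownian_ensemble.tracks[:5], 10.0)
        a = feature_table(ts, FeatureParams(rw_n_sim=10))
        b = feature_table(ts, FeatureParams(rw_n_sim=10))
        assert a.equals(b)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            feature_table(TrackSet([], 10.0))
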