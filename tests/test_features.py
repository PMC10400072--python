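"""Trajectory features: speed, turn rate, curvature, handedness,
navigation index, stitching, peri-event averages."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from larvatrack.features import (TurnStatistics, compute_curvature,
                                 compute_speed, compute_turn_rate,
                                 navigation_index, navigation_index_series,
                                 perievent_average, stitch_trajectory,
                                 turn_handedness)


class TestSpeed:
    def test_uniform_motion(self):
        x = np.arange(100) * 0.5        # 0.5 mm/frame at 10 Hz = 5 mm/s
        s = compute_speed(x, np.zeros(100), 10.0, window_s=1.0)
        assert np.allclose(s, 5.0)

    def test_stationary(self):
        s = compute_speed(np.zeros(50), np.zeros(50), 10.0)
        assert np.allclose(s, 0.0)

    def test_too_small_window_rejected(self):
        with pytest.raises(ValueError):
            compute_speed(np.zeros(10), np.zeros(10), 10.0, window_s=0.01)

    def test_invalid_frames_are_nan(self):
        x = np.arange(50) * 0.1
        valid = np.ones(50, bool)
        valid[20:30] = False
        s = compute_speed(x, np.zeros(50), 10.0, valid=valid)
        assert np.isnan(s[24])
        assert np.isfinite(s[5])

    def test_recovers_configured_speed_decay(self):
        from larvatrack.config import SimConfig
        from larvatrack.simulate import simulate_trajectories

        sim = SimConfig(n_animals=3, arena_side=200.0, duration=600.0,
                        mean_speed=0.7, speed_decay=5e-4, turn_rate=2.0,
                        collision_rate=0.0, occlusion_rate=0.0, rng_seed=29)
        truth = simulate_trajectories(sim)
        slopes = []
        for _, g in truth.frames.groupby("id"):
            run = g["state"].to_numpy() == "run"
            s = compute_speed(g["x_mm"].to_numpy(), g["y_mm"].to_numpy(),
                              sim.frame_rate, 1.0)
            t = g["frame"].to_numpy() / sim.frame_rate
            ok = run & np.isfinite(s)
            slopes.append(np.polyfit(t[ok], s[ok], 1)[0])
        assert np.mean(slopes) == pytest.approx(-sim.speed_decay, rel=0.10)


class TestTurnRate:
    def test_zero_events(self):
        assert np.allclose(compute_turn_rate([], 100, 10.0), 0.0)

    def test_poisson_events_recover_rate(self):
        rng = np.random.default_rng(3)
        lam = 4.0                        # events per minute
        n = 60000                        # 100 minutes at 10 Hz
        p = lam / 60.0 / 10.0
        onsets = np.flatnonzero(rng.random(n) < p)
        series = compute_turn_rate(onsets, n, 10.0, window_s=300.0)
        se = np.sqrt(len(onsets)) / (n / 10.0 / 60.0)
        assert np.mean(series) == pytest.approx(lam, abs=3 * se)


class TestCurvature:
    def test_straight_path_zero(self):
        c = compute_curvature(np.linspace(0, 30, 100), np.zeros(100), 1.0)
        assert np.allclose(c, 0.0, atol=1e-9)

    def test_circle_curvature_is_inverse_radius(self):
        R = 7.0
        th = np.linspace(0, 4 * np.pi, 4000)
        c = compute_curvature(R * np.cos(th), R * np.sin(th), 0.5)
        assert np.mean(np.abs(c)) == pytest.approx(1.0 / R, rel=0.02)

    def test_sign_matches_turn_direction(self):
        # counterclockwise (left, y-up) circle -> positive curvature
        th = np.linspace(0, np.pi, 500)
        c = compute_curvature(5 * np.cos(th), 5 * np.sin(th), 0.5)
        assert (c > 0).all()

    def test_short_path_rejected(self):
        with pytest.raises(ValueError):
            compute_curvature([0, 0.1], [0, 0], 1.0)


class TestHandedness:
    @pytest.mark.parametrize("left,right,want", [
        (10, 0, 1.0), (0, 10, -1.0), (7, 3, 0.4)])
    def test_formula(self, left, right, want):
        ev = pd.DataFrame({"direction": ["left"] * left + ["right"] * right,
                           "size_deg": [30.0] * left + [-30.0] * right})
        stats = turn_handedness(ev)
        assert stats.handedness == pytest.approx(want)
        assert stats.n_total == left + right

    def test_no_events_undefined(self):
        stats = turn_handedness(pd.DataFrame(columns=["direction"]))
        assert np.isnan(stats.handedness)

    def test_ambiguous_turns_counted_separately(self):
        ev = pd.DataFrame({"direction": ["left", "none", "right", "left"]})
        stats = turn_handedness(ev)
        assert stats.n_total == 3 and stats.n_ambiguous == 1

    def test_antisymmetric_under_mirror(self):
        ev = pd.DataFrame({"direction": ["left"] * 6 + ["right"] * 2})
        mirrored = ev.replace({"left": "right", "right": "left"})
        assert turn_handedness(ev).handedness == \
            -turn_handedness(mirrored).handedness


class TestNavigationIndex:
    def test_parallel_and_antiparallel(self):
        x = np.arange(100) * 0.05
        assert navigation_index(x, 0 * x, 10.0) == pytest.approx(1.0)
        assert navigation_index(-x, 0 * x, 10.0) == pytest.approx(-1.0)

    def test_closed_loop_is_zero(self):
        th = np.linspace(0, 6 * np.pi, 3001)   # integer number of periods
        ni = navigation_index(np.cos(th), np.sin(th), 10.0)
        assert ni == pytest.approx(0.0, abs=1e-12)

    def test_stationary_undefined(self):
        assert np.isnan(navigation_index(np.zeros(10), np.zeros(10), 10.0))

    @settings(max_examples=40, deadline=None)
    @given(seed=hst.integers(0, 2 ** 20))
    def test_bounded_by_one_on_random_walks(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 50)).cumsum(axis=1)
        ni = navigation_index(x, y, 10.0)
        assert -1.0 <= ni <= 1.0 + 1e-12

    def test_windowed_series_flags_motionless_windows(self):
        x = np.concatenate([np.arange(50) * 0.1, np.full(50, 4.9)])
        df = navigation_index_series(x, np.zeros(100), 10.0, window_s=5.0)
        assert df["index"].iloc[0] == pytest.approx(1.0)
        assert np.isnan(df["index"].iloc[1])


class TestStitching:
    def test_two_straight_segments_join_continuously(self):
        x = np.concatenate([np.arange(0, 1001.0), 5000 + np.arange(0, 1001.0)])
        y = np.zeros(len(x))
        sx, sy, length = stitch_trajectory(x, y, [1001])
        assert length == pytest.approx(2.0)      # two 1 m arms in meters
        assert np.abs(np.diff(sx)).max() == pytest.approx(1.0)

    def test_translation_only_keeps_headings(self):
        rng = np.random.default_rng(8)
        x, y = rng.standard_normal((2, 60)).cumsum(axis=1)
        sx, sy, _ = stitch_trajectory(x, y, [20, 40])
        for s in (slice(0, 20), slice(20, 40), slice(40, 60)):
            assert np.allclose(np.diff(sx[s]), np.diff(x[s]))
            assert np.allclose(np.diff(sy[s]), np.diff(y[s]))

    def test_length_invariant_to_relocation_placement(self):
        rng = np.random.default_rng(9)
        steps = rng.standard_normal((2, 100))
        x, y = steps.cumsum(axis=1)
        _, _, l1 = stitch_trajectory(x, y, [30])
        x2 = x.copy()
        x2[60:] += 500.0                          # relocation elsewhere
        _, _, l2 = stitch_trajectory(x2, y, [30, 60])
        base = np.hypot(np.diff(x), np.diff(y))
        assert l1 == pytest.approx(np.delete(base, 29).sum() / 1000.0)
        assert l2 <= l1


class TestPerievent:
    def test_constant_series_flat(self):
        lags, mean, sd, n = perievent_average(np.full(500, 3.0), [100, 300],
                                              10.0, 5.0, 5.0)
        assert np.allclose(mean, 3.0) and np.allclose(sd, 0.0) and n == 2

    def test_edge_events_excluded(self):
        lags, mean, sd, n = perievent_average(np.arange(200.0), [2, 100, 199],
                                              10.0, 5.0, 5.0)
        assert n == 1

    def test_no_valid_events_rejected(self):
        with pytest.raises(ValueError):
            perievent_average(np.arange(10.0), [0], 10.0, 5.0, 5.0)

    def test_recovers_injected_transient_time_constant(self):
        rng = np.random.default_rng(12)
        fr, tau = 10.0, 8.0
        series = np.zeros(20000) + rng.normal(0, 0.02, 20000)
        events = np.arange(500, 19500, 1000)
        t = np.arange(0, 300) / fr
        for ev in events:
            series[ev:ev + 300] += np.exp(-t / tau)
        lags, mean, sd, n = perievent_average(series, events, fr, 10.0, 25.0)
        post = mean[lags >= 0]
        post_t = lags[lags >= 0]
        # time to decay to 1/e of the step estimates tau
        tau_hat = post_t[np.argmax(post < post[0] / np.e)]
        assert tau_hat == pytest.approx(tau, rel=0.2)


def test_correlated_speed_and_turn_rate_under_shared_decay():
    """A shared slow-down in the simulator induces positive correlation
    between the population speed and turn-rate series."""
    from larvatrack.config import SimConfig
    from larvatrack.simulate import simulate_trajectories
    from larvatrack.stats import series_correlation

    sim = SimConfig(n_animals=4, arena_side=200.0, duration=900.0,
                    mean_speed=0.9, speed_decay=6e-4, turn_rate=6.0,
                    collision_rate=0.0, occlusion_rate=0.0, rng_seed=37)
    # emulate the paired activity drop: thin the turn schedule in proportion
    # to the speed decline
    truth = simulate_trajectories(sim)
    n = truth.n_frames
    speeds = np.zeros(n)
    for _, g in truth.frames.groupby("id"):
        s = compute_speed(g["x_mm"].to_numpy(), g["y_mm"].to_numpy(),
                          sim.frame_rate, 1.0)
        speeds += np.nan_to_num(s) / sim.n_animals
    frac = np.linspace(1.0, 0.3, n)
    rng = np.random.default_rng(0)
    onsets = truth.turns["frame"].to_numpy()
    kept = onsets[rng.random(len(onsets)) < frac[onsets]]
    rate = compute_turn_rate(kept, n, sim.frame_rate, window_s=120.0)
    # compare minute-binned series
    nbin = n // 600
    sp = speeds[:nbin * 600].reshape(nbin, 600).mean(axis=1)
    tr = rate[:nbin * 600].reshape(nbin, 600).mean(axis=1)
    assert series_correlation(sp, tr) > 0.3


def test_turn_statistics_invariants():
    stats = TurnStatistics(n_left=3, n_right=5)
    assert stats.n_total == 8
    assert -1.0 <= stats.handedness <= 1.0
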