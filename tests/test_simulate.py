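"""Simulator: trajectory statistics, rendering contracts, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from larvatrack.config import SimConfig, VariabilityModel
from larvatrack.simulate import (render_array, render_video,
                                 simulate_trajectories, simulate_variability)
from scipy import ndimage


def test_no_turns_gives_straight_path_of_expected_length():
    cfg = SimConfig(n_animals=1, arena_side=200.0, duration=60.0,
                    turn_rate=0.0, speed_decay=0.0, heading_jitter_sd=0.0,
                    collision_rate=0.0, occlusion_rate=0.0, rng_seed=3)
    truth = simulate_trajectories(cfg)
    g = truth.frames.sort_values("frame")
    steps = np.hypot(np.diff(g["x_mm"]), np.diff(g["y_mm"]))
    # length of the travelled path (first step happens at frame 1)
    expected = cfg.mean_speed * (cfg.duration - 1.0 / cfg.frame_rate)
    assert steps.sum() == pytest.approx(expected, rel=1e-6)
    # perfectly straight: collinear displacements
    assert np.ptp(np.arctan2(np.diff(g["y_mm"]), np.diff(g["x_mm"]))) < 1e-9
    assert len(truth.turns) == 0


def test_full_handedness_bias_makes_every_turn_left():
    cfg = SimConfig(n_animals=2, arena_side=100.0, duration=300.0,
                    handedness_bias=1.0, turn_rate=6.0, collision_rate=0.0,
                    occlusion_rate=0.0, rng_seed=5)
    truth = simulate_trajectories(cfg)
    assert len(truth.turns) > 10
    assert (truth.turns["dtheta_deg"] > 0).all()


def test_unbiased_turns_have_zero_mean_within_three_se():
    cfg = SimConfig(n_animals=4, arena_side=150.0, duration=1800.0,
                    turn_rate=20.0, turn_duration=0.3, handedness_bias=0.0,
                    gradient_bias=0.0, collision_rate=0.0, occlusion_rate=0.0,
                    rng_seed=11)
    truth = simulate_trajectories(cfg)
    d = truth.turns["dtheta_deg"].to_numpy()
    assert len(d) > 1000
    se = d.std(ddof=1) / np.sqrt(len(d))
    assert abs(d.mean()) < 3 * se


def test_turn_rate_is_ergodic():
    """Empirical turn rate over run time converges to the configured rate."""
    cfg = SimConfig(n_animals=4, arena_side=150.0, duration=900.0,
                    turn_rate=6.0, collision_rate=0.0, occlusion_rate=0.0,
                    rng_seed=13)
    truth = simulate_trajectories(cfg)
    n_turns = len(truth.turns)
    run_minutes = (truth.frames["state"] == "run").sum() / cfg.frame_rate / 60.0
    rate = n_turns / run_minutes
    # Poisson sampling error
    assert rate == pytest.approx(cfg.turn_rate,
                                 abs=3 * np.sqrt(n_turns) / run_minutes)


def test_same_seed_is_bit_identical():
    cfg = SimConfig(n_animals=3, arena_side=60.0, duration=20.0,
                    noise_sd=2.0, background_drift=0.05, rng_seed=21)
    t1 = simulate_trajectories(cfg)
    t2 = simulate_trajectories(cfg)
    pd.testing.assert_frame_equal(t1.frames, t2.frames)
    pd.testing.assert_frame_equal(t1.turns, t2.turns)
    v1 = render_array(t1)
    v2 = render_array(t2)
    assert (v1 == v2).all()


def test_turn_log_lies_inside_turn_blocks():
    cfg = SimConfig(n_animals=2, arena_side=80.0, duration=300.0,
                    turn_rate=6.0, collision_rate=0.0, occlusion_rate=0.0,
                    rng_seed=2)
    truth = simulate_trajectories(cfg)
    states = {(int(r.frame), int(r.id)): r.state
              for r in truth.frames.itertuples()}
    # the logged frame is the last frame of its turn block
    for r in truth.turns.itertuples():
        assert states[(int(r.frame), int(r.id))] == "turn"


class TestRendering:
    def test_single_animal_single_component(self, quiet_sim):
        cfg = SimConfig(**{**quiet_sim.__dict__, "n_animals": 1,
                           "duration": 5.0})
        video = render_array(simulate_trajectories(cfg))
        for frame in video:
            _, n = ndimage.label(frame > 100)
            assert n == 1

    def test_blob_pixel_count_in_expected_band(self, quiet_sim):
        cfg = SimConfig(**{**quiet_sim.__dict__, "n_animals": 1,
                           "duration": 5.0})
        video = render_array(simulate_trajectories(cfg))
        for frame in video:
            assert 20 <= (frame > 100).sum() <= 45

    def test_rendered_centroid_matches_true_position(self, quiet_sim):
        cfg = SimConfig(**{**quiet_sim.__dict__, "n_animals": 1,
                           "duration": 5.0})
        truth = simulate_trajectories(cfg)
        from larvatrack.config import mm_to_px
        for (t, frame), row in zip(render_video(truth),
                                   truth.frames.itertuples()):
            ys, xs = np.nonzero(frame > 100)
            ex, ey = mm_to_px(row.x_mm, row.y_mm, cfg.arena_side,
                              cfg.px_per_mm)
            assert np.hypot(xs.mean() - ex, ys.mean() - ey) < 0.5

    def test_occluded_animal_leaves_no_bright_component(self):
        cfg = SimConfig(n_animals=1, arena_side=40.0, duration=60.0,
                        occlusion_rate=200.0, occlusion_duration=2.0,
                        collision_rate=0.0, noise_sd=0.0,
                        background_drift=0.0, rng_seed=9)
        truth = simulate_trajectories(cfg)
        hidden = truth.frames[~truth.frames["visible"]]
        assert len(hidden) > 0
        video = render_array(truth)
        for r in hidden.itertuples():
            assert (video[int(r.frame)] > 100).sum() == 0

    def test_sub_detectable_scale_rejected(self, quiet_sim):
        cfg = SimConfig(**{**quiet_sim.__dict__, "px_per_mm": 1.0,
                           "duration": 2.0})
        truth = simulate_trajectories(cfg)
        with pytest.raises(ValueError, match="3 px"):
            next(iter(render_video(truth)))


class TestVariabilityModel:
    def test_zero_inter_sigma_gives_identical_means(self):
        m = VariabilityModel(sigma_inter=0.0, rng_seed=1)
        _, mu = simulate_variability(m)
        assert np.allclose(mu, m.mu_population)

    def test_zero_intra_sigma_gives_constant_observations(self):
        m = VariabilityModel(sigma_intra=0.0, rng_seed=1)
        obs, mu = simulate_variability(m)
        assert np.allclose(obs, mu[:, None])

    def test_clustered_means_give_multimodal_mean_of_intra(self):
        from larvatrack.stats import (bimodality_coefficient,
                                      intra_inter_decomposition)
        m = VariabilityModel(n_animals=40, sigma_intra=0.3, sigma_inter=0.03,
                             mu_modes=(-0.1, 0.55), rng_seed=4)
        obs, _ = simulate_variability(m)
        dec = intra_inter_decomposition(obs)
        assert bimodality_coefficient(dec.animal_means).bc > 5.0 / 9.0

    def test_gradient_bias_raises_navigation_index(self):
        from larvatrack.features import navigation_index
        base = dict(n_animals=3, arena_side=150.0, duration=600.0,
                    turn_rate=8.0, collision_rate=0.0, occlusion_rate=0.0,
                    rng_seed=6)
        for bias, lo, hi in ((0.0, -0.25, 0.25), (3.0, 0.1, 1.0)):
            truth = simulate_trajectories(SimConfig(gradient_bias=bias, **base))
            navs = [navigation_index(g["x_mm"], g["y_mm"], 10.0)
                    for _, g in truth.frames.groupby("id")]
            assert lo < np.mean(navs) < hi
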