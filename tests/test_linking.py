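"""Linking loss, greedy assignment, interpolation, collision resolution."""

import numpy as np
import pytest

from larvatrack.background import Detection
from larvatrack.config import LinkingConfig, PipelineConfig, SimConfig, \
    BackgroundConfig
from larvatrack.linking import (Track, assign_identities, detect_collision,
                                interpolate_gap, link_loss, resolve_collision)


def make_det(x, y, area=30.0, frame=1):
    mask = np.ones((3, 3), bool)
    return Detection(centroid=(x, y), area=area, frame_index=frame,
                     contour=np.empty((0, 2)), mask=mask,
                     offset=(int(x) - 1, int(y) - 1))


def make_track(tid, positions, area=30.0):
    tr = Track(id=tid)
    for k, (x, y) in enumerate(positions):
        tr.append(k, x, y, area)
    return tr


class TestLinkLoss:
    def test_identical_state_gives_zero(self):
        tr = make_track(0, [(5.0, 5.0), (5.0, 5.0)])
        det = make_det(5.0, 5.0)
        cfg = LinkingConfig()
        assert link_loss(det, tr, cfg) == 0.0

    def test_three_four_five_displacement(self):
        tr = make_track(0, [(0.0, 0.0), (0.0, 0.0)])
        det = make_det(3.0, 4.0)
        cfg = LinkingConfig(beta_r=1.0, beta_p=0.0, beta_a=0.0)
        assert link_loss(det, tr, cfg) == pytest.approx(5.0)

    def test_matches_bruteforce_formula_on_randomized_cases(self):
        """1000 random states agree with an independent re-evaluation of
        beta_r*D(r) + beta_p*D(p) + beta_a*D(a) to machine precision."""
        rng = np.random.default_rng(3)
        for _ in range(1000):
            cfg = LinkingConfig(beta_r=rng.uniform(0, 2),
                                beta_p=rng.uniform(0, 2),
                                beta_a=rng.uniform(0, 0.1) + 1e-6)
            pos = rng.uniform(0, 100, size=(4, 2))
            tr = make_track(0, pos, area=rng.uniform(10, 50))
            det = make_det(*rng.uniform(0, 100, size=2),
                           area=rng.uniform(10, 50))
            # independent oracle, written directly from the definition
            r_j = pos[-1]
            k = min(cfg.momentum_window, len(pos) - 1)
            p_j = (pos[-1] - pos[-1 - k]) / k
            r_i = np.array(det.centroid)
            p_i = r_i - r_j
            want = (cfg.beta_r * np.linalg.norm(r_i - r_j)
                    + cfg.beta_p * np.linalg.norm(p_i - p_j)
                    + cfg.beta_a * abs(det.area - tr.a))
            assert link_loss(det, tr, cfg) == pytest.approx(want, abs=1e-12)


class TestGreedyAssignment:
    def test_single_pair_within_gate(self):
        tr = make_track(0, [(0, 0), (1, 0)])
        det = make_det(2.0, 0.0)
        matches, ut, ud = assign_identities([det], [tr], LinkingConfig())
        assert matches == {0: 0} and ut == [] and ud == []

    def test_pair_beyond_gate_left_unmatched(self):
        tr = make_track(0, [(0, 0)])
        det = make_det(500.0, 500.0)
        matches, ut, ud = assign_identities([det], [tr],
                                            LinkingConfig(max_loss=60.0))
        assert matches == {} and ut == [0] and ud == [0]

    def test_greedy_differs_from_optimal_assignment(self):
        """Constructed case where lowest-loss-first is not globally optimal:
        the greedy result (not the optimum) must be returned."""
        cfg = LinkingConfig(beta_r=1.0, beta_p=0.5, beta_a=0.0,
                            max_loss=1e9)
        t0 = make_track(0, [(0.0, 0.0), (0.0, 0.0)])      # momentum (0, 0)
        t1 = make_track(1, [(3.0, 0.0), (2.0, 0.0)])      # momentum (-1, 0)
        d0 = make_det(1.0, 0.0)
        d1 = make_det(5.0, 0.0)
        # loss matrix (tracks x dets):
        # L(t0,d0)=1+0.5*1=1.5   L(t0,d1)=5+2.5=7.5
        # L(t1,d0)=1+0.5*0=1.0   L(t1,d1)=3+0.5*4=5.0
        losses = {(t.id, d): link_loss(det, t, cfg)
                  for t in (t0, t1) for d, det in enumerate((d0, d1))}
        assert losses[(1, 0)] == pytest.approx(1.0)
        assert losses[(0, 0)] == pytest.approx(1.5)
        # oracle: enumerate both complete assignments
        greedy_total = losses[(1, 0)] + losses[(0, 1)]    # 1.0 + 7.5
        optimal_total = losses[(0, 0)] + losses[(1, 1)]   # 1.5 + 5.0
        assert optimal_total < greedy_total
        matches, _, _ = assign_identities([d0, d1], [t0, t1], cfg)
        assert matches == {1: 0, 0: 1}                    # greedy, not optimal

    def test_deterministic_tie_break_prefers_lower_ids(self):
        cfg = LinkingConfig(beta_r=1.0, beta_p=0.0, beta_a=0.0, max_loss=10)
        t0 = make_track(0, [(0.0, 0.0)])
        t1 = make_track(1, [(2.0, 0.0)])
        d0 = make_det(1.0, 0.0)     # distance 1 from both tracks
        matches, _, _ = assign_identities([d0], [t0, t1], cfg)
        assert matches == {0: 0}

    def test_empty_inputs(self):
        assert assign_identities([], [], LinkingConfig()) == ({}, [], [])


class TestInterpolation:
    def test_linear_fill_of_four_frame_gap(self):
        filled = interpolate_gap((0.0, 0.0), (10.0, 0.0), 4)
        assert np.allclose(filled, [(2, 0), (4, 0), (6, 0), (8, 0)])

    def test_zero_gap_is_noop(self):
        assert interpolate_gap((0, 0), (1, 1), 0).shape == (0, 2)

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            interpolate_gap((0, 0), (1, 1), -1)

    def test_occlusion_gap_interpolated_within_one_body_length(self):
        """A 4.5 s (45-frame) camera occlusion during straight crawling is
        bridged with sub-body-length error."""
        from larvatrack.pipeline import track_video
        from larvatrack.simulate import render_video, simulate_trajectories

        sim = SimConfig(n_animals=1, arena_side=60.0, duration=40.0,
                        turn_rate=0.0, heading_jitter_sd=0.0,
                        occlusion_rate=200.0, occlusion_duration=4.5,
                        relocate_on_occlusion=False, collision_rate=0.0,
                        rng_seed=23)
        truth = simulate_trajectories(sim)
        assert (~truth.frames["visible"]).sum() >= 45
        cfg = PipelineConfig(sim=sim, background=BackgroundConfig(init="median"))
        tracks, _ = track_video(render_video(truth), cfg, with_posture=False)
        interp = tracks[tracks["interpolated"]]
        assert len(interp) >= 40
        tf = truth.frames.set_index("frame")
        for row in interp.itertuples():
            err = np.hypot(row.x_mm - tf.loc[row.frame, "x_mm"],
                           row.y_mm - tf.loc[row.frame, "y_mm"])
            assert err < sim.body_length


class TestCollision:
    def _colliding_setup(self):
        mask = np.zeros((9, 9), bool)
        mask[2:7, 1:8] = True
        merged = Detection(centroid=(30.0, 30.0), area=200.0, frame_index=5,
                           contour=np.empty((0, 2)), mask=mask,
                           offset=(26, 26))
        t0 = make_track(0, [(24.0, 28.0), (26.0, 29.0), (28.0, 30.0)])
        t1 = make_track(1, [(36.0, 32.0), (34.0, 31.0), (32.0, 30.0)])
        for tr in (t0, t1):
            tr.last_mask = np.ones((4, 4), bool)
            tr.last_mask_offset = (int(tr.r[0]) - 2, int(tr.r[1]) - 2)
        return merged, t0, t1

    def test_two_converging_tracks_open_one_event(self):
        merged, t0, t1 = self._colliding_setup()
        events = detect_collision([merged], [t0, t1], LinkingConfig(),
                                  max_single_area=120.0)
        assert len(events) == 1
        assert sorted(events[0].participants) == [0, 1]

    def test_no_oversized_detection_no_event(self):
        _, t0, t1 = self._colliding_setup()
        small = make_det(30.0, 30.0, area=50.0)
        assert detect_collision([small], [t0, t1], LinkingConfig(),
                                max_single_area=120.0) == []

    def test_perfect_overlap_recovers_known_shifts(self):
        """Merged mask constructed as the union of shifted priors: the
        optimizer must recover exactly those shifts."""
        rng = np.random.default_rng(5)
        a = rng.random((7, 5)) > 0.3
        b = rng.random((6, 8)) > 0.3
        a[3, 2] = b[3, 4] = True
        true_shift = {0: np.array([4, 2]), 1: np.array([-3, 1])}
        canvas = np.zeros((30, 30), bool)
        canvas[10 + 2:17 + 2, 10 + 4:15 + 4] |= a     # prior 0 at (10,10)+shift
        canvas[12 + 1:18 + 1, 14 - 3:22 - 3] |= b     # prior 1 at (14,12)+shift
        priors = {0: (a, (10, 10)), 1: (b, (14, 12))}
        init = {0: np.array([3, 3]), 1: np.array([-2, 0])}  # off by <=2 px
        positions, shifts, status = resolve_collision(
            priors, init, canvas, (0, 0), max_epochs=50)
        assert status == "resolved"
        assert np.array_equal(shifts[0], true_shift[0])
        assert np.array_equal(shifts[1], true_shift[1])

    def test_single_participant_degenerates_to_translation_match(self):
        a = np.ones((4, 6), bool)
        canvas = np.zeros((20, 20), bool)
        canvas[8:12, 7:13] = True
        positions, shifts, status = resolve_collision(
            {0: (a, (2, 3))}, {0: np.array([5, 4])}, canvas, (0, 0))
        assert status == "resolved"
        # prior occupies x 2..7, y 3..6; target x 7..12, y 8..11
        assert np.array_equal(shifts[0], [5, 5])

    def test_hopeless_overlap_falls_back_to_momentum(self):
        a = np.ones((3, 3), bool)
        canvas = np.zeros((10, 10), bool)
        canvas[0:2, 0:2] = True
        init = {0: np.array([100, 100])}
        positions, shifts, status = resolve_collision(
            {0: (a, (50, 50))}, init, canvas, (200, 200), max_epochs=3)
        assert status == "fallback"
        assert np.array_equal(shifts[0], init[0])


def test_identity_conservation_and_determinism():
    """Track count never exceeds n_animals; identical input, identical output."""
    from larvatrack.pipeline import track_video
    from larvatrack.simulate import render_video, simulate_trajectories

    sim = SimConfig(n_animals=3, arena_side=50.0, duration=30.0,
                    collision_rate=0.0, occlusion_rate=0.0, rng_seed=31)
    cfg = PipelineConfig(sim=sim, background=BackgroundConfig(init="median"))
    truth = simulate_trajectories(sim)
    df1, _ = track_video(render_video(truth), cfg, with_posture=False)
    df2, _ = track_video(render_video(truth), cfg, with_posture=False)
    assert df1.equals(df2)
    per_frame_ids = df1.groupby("frame")["id"].nunique()
    assert (df1.groupby("frame")["id"].count() == per_frame_ids).all()
    assert df1["id"].nunique() <= sim.n_animals
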