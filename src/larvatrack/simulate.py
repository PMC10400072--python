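"""Synthetic larva arena: run-and-turn trajectories, rendered video frames,
and the Gaussian intra-/inter-animal variability toy model.

The generator produces exhaustive ground truth (positions, headings,
behavioral states, head/tail keypoints, turn log, event log) so that every
downstream stage — detection, identity linking, posture, behavior
segmentation, navigation statistics — can be validated without recorded
data.

Trajectories follow a run-and-turn random walk: forward crawling at a
(possibly slowly drifting) speed with small von Mises heading diffusion,
interrupted by pause-like turns whose signed heading change is drawn with a
configurable left/right bias and wrapped-normal magnitude.  A gradient bias
parameter tilts post-turn headings toward +x, producing a controllable
navigation index.  Robot pick-up events are emulated as occlusion gaps
followed by relocation to the arena centre (translation only, heading
preserved); pairwise collisions steer two animals through a common point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimConfig, VariabilityModel, mm_to_px

__all__ = [
    "GroundTruth",
    "simulate_trajectories",
    "render_video",
    "render_array",
    "body_polyline",
    "simulate_variability",
]

RUN, TURN = "run", "turn"


@dataclass
class GroundTruth:
    """Per-frame per-animal truth plus turn and event logs.

    ``frames`` columns: frame, id, x_mm, y_mm, heading (rad, y-up metric
    convention), bend (rad, signed body bend), state (run|turn), visible,
    head_x_mm, head_y_mm, tail_x_mm, tail_y_mm.
    ``turns`` columns: id, frame, dtheta_deg (signed, positive = left/CCW).
    ``events`` columns: kind (relocation|collision), id, id2, start_frame,
    end_frame, x_mm, y_mm.
    """

    frames: pd.DataFrame
    turns: pd.DataFrame
    events: pd.DataFrame
    config: SimConfig

    @property
    def n_frames(self) -> int:
        return int(self.frames["frame"].max()) + 1 if len(self.frames) else 0


def _wrap(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) to (-pi, pi]."""
    return -((np.pi - np.asarray(angle)) % (2.0 * np.pi)) + np.pi


def body_polyline(x: float, y: float, heading: float, bend: float,
                  length: float, n: int = 9) -> np.ndarray:
    """Body axis polyline (tail -> head) of a larva centred at (x, y).

    The body is a constant-curvature arc of total turning ``bend`` whose
    tangent at the centre equals ``heading``; bend 0 gives a straight body.
    Returns an (n, 2) array in the same units as ``length``.
    """
    s = np.linspace(-0.5, 0.5, n)              # arc-length fraction, tail->head
    ds = length / (n - 1)
    dirs = heading + bend * s                  # tangent direction along the body
    # midpoint-rule integration outward from the centre
    pts = np.empty((n, 2))
    mid = (n - 1) // 2
    pts[mid] = (x, y)
    for k in range(mid, n - 1):
        d = 0.5 * (dirs[k] + dirs[k + 1])
        pts[k + 1] = pts[k] + ds * np.array([np.cos(d), np.sin(d)])
    for k in range(mid, 0, -1):
        d = 0.5 * (dirs[k] + dirs[k - 1])
        pts[k - 1] = pts[k] - ds * np.array([np.cos(d), np.sin(d)])
    return pts


def simulate_trajectories(config: SimConfig) -> GroundTruth:
    """Generate run-and-turn ground-truth trajectories for all animals."""
    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed).spawn(2)[0])
    n_frames = config.n_frames
    dt = 1.0 / config.frame_rate
    half = config.arena_side / 2.0
    margin = max(2.0 * config.body_length, 0.02 * config.arena_side)
    p_turn = config.turn_rate / 60.0 * dt      # per-frame turn onset probability
    turn_frames = max(1, int(round(config.turn_duration * config.frame_rate)))
    jitter_sd = np.deg2rad(config.heading_jitter_sd)
    kappa_jitter = 1.0 / jitter_sd**2 if jitter_sd > 0 else np.inf
    centre = np.array([half, half])

    # Poisson event schedules ------------------------------------------------
    duration_h = config.duration / 3600.0
    occl: dict[int, list[int]] = {}
    for i in range(config.n_animals):
        k = rng.poisson(config.occlusion_rate * duration_h)
        occl[i] = sorted(rng.integers(turn_frames, max(turn_frames + 1, n_frames - 10),
                                      size=k).tolist())
    n_coll = rng.poisson(config.collision_rate * duration_h) if config.n_animals >= 2 else 0
    coll_sched = []
    coll_frames = max(2, int(round(config.collision_duration * config.frame_rate)))
    for _ in range(n_coll):
        t0 = int(rng.integers(coll_frames, max(coll_frames + 1, n_frames - coll_frames)))
        i, j = rng.choice(config.n_animals, size=2, replace=False)
        coll_sched.append((t0, int(i), int(j)))

    occl_gap = max(1, int(round(config.occlusion_duration * config.frame_rate)))

    cols_x = np.empty((n_frames, config.n_animals))
    cols_y = np.empty((n_frames, config.n_animals))
    cols_h = np.empty((n_frames, config.n_animals))
    cols_b = np.zeros((n_frames, config.n_animals))
    cols_state = np.empty((n_frames, config.n_animals), dtype=object)
    cols_vis = np.ones((n_frames, config.n_animals), dtype=bool)

    turn_log: list[tuple[int, int, float]] = []
    event_log: list[dict] = []

    for i in range(config.n_animals):
        pos = centre + rng.uniform(-0.3, 0.3, size=2) * config.arena_side
        heading = rng.uniform(-np.pi, np.pi)
        state = RUN
        frames_left = 0          # remaining frames of the current turn/occlusion
        pending_turn = 0.0
        occl_left = 0
        occl_queue = list(occl[i])
        bend_target = 0.0

        for t in range(n_frames):
            # -------- robot pick-up: occlusion gap then relocation ----------
            if occl_left == 0 and occl_queue and t >= occl_queue[0]:
                occl_queue.pop(0)
                occl_left = occl_gap
                event_log.append(dict(kind="relocation", id=i, id2=-1,
                                      start_frame=t, end_frame=t + occl_gap,
                                      x_mm=pos[0], y_mm=pos[1]))
            occluded = occl_left > 0
            frame_state = state          # state at frame start (pre-transition)
            if occluded:
                occl_left -= 1
                cols_vis[t, i] = False
                if occl_left == 0 and config.relocate_on_occlusion:
                    pos = centre.copy()
            if occluded and config.relocate_on_occlusion:
                pass   # held by the robot: no crawling during the gap
            elif state == RUN:
                v = max(config.mean_speed - config.speed_decay * t * dt, 0.05)
                step = v * dt
                pos = pos + step * np.array([np.cos(heading), np.sin(heading)])
                if jitter_sd > 0:
                    heading = _wrap(heading + rng.vonmises(0.0, kappa_jitter))
                # reflect off the arena walls
                for ax in (0, 1):
                    if pos[ax] < margin:
                        pos[ax] = 2 * margin - pos[ax]
                        heading = _wrap(np.pi - heading if ax == 0 else -heading)
                    elif pos[ax] > config.arena_side - margin:
                        pos[ax] = 2 * (config.arena_side - margin) - pos[ax]
                        heading = _wrap(np.pi - heading if ax == 0 else -heading)
                if rng.random() < p_turn:
                    state = TURN
                    frames_left = turn_frames
                    sign = 1.0 if rng.random() < (1.0 + config.handedness_bias) / 2.0 else -1.0
                    mag = abs(rng.normal(config.turn_size_mean,
                                         config.turn_size_dispersion))
                    mag = min(mag, 175.0)
                    pending_turn = sign * np.deg2rad(mag)
                    bend_target = np.clip(pending_turn, -np.pi / 2, np.pi / 2)
            else:  # TURN: pause with the body bending toward the new heading
                frames_left -= 1
                prog = 1.0 - frames_left / turn_frames
                cols_b[t, i] = bend_target * np.sin(np.pi * min(prog, 1.0))
                if frames_left == 0:
                    old = heading
                    heading = _wrap(heading + pending_turn)
                    if config.gradient_bias > 0:
                        w = config.gradient_bias / (1.0 + config.gradient_bias)
                        if rng.random() < w:
                            heading = _wrap(rng.vonmises(0.0, 2.0))
                    turn_log.append((i, t, float(np.rad2deg(_wrap(heading - old)))))
                    state = RUN

            cols_x[t, i], cols_y[t, i] = pos
            cols_h[t, i] = heading
            cols_state[t, i] = frame_state

    # -------- engineered pairwise crossings ---------------------------------
    for (t0, i, j) in coll_sched:
        t1 = min(t0 + coll_frames, n_frames - 1)
        mid = (t0 + t1) // 2
        target = np.array([cols_x[mid, i], cols_y[mid, i]])
        natural = np.array([cols_x[mid, j], cols_y[mid, j]])
        offset = target - natural
        w = np.concatenate([np.linspace(0, 1, mid - t0 + 1),
                            np.linspace(1, 0, t1 - mid + 1)[1:]])
        cols_x[t0:t1 + 1, j] += offset[0] * w
        cols_y[t0:t1 + 1, j] += offset[1] * w
        event_log.append(dict(kind="collision", id=i, id2=j,
                              start_frame=t0, end_frame=t1,
                              x_mm=target[0], y_mm=target[1]))

    np.clip(cols_x, 0.5, config.arena_side - 0.5, out=cols_x)
    np.clip(cols_y, 0.5, config.arena_side - 0.5, out=cols_y)

    # -------- head/tail keypoints from the body arc -------------------------
    head = np.empty((n_frames, config.n_animals, 2))
    tail = np.empty((n_frames, config.n_animals, 2))
    for i in range(config.n_animals):
        for t in range(n_frames):
            pts = body_polyline(cols_x[t, i], cols_y[t, i], cols_h[t, i],
                                cols_b[t, i], config.body_length, n=5)
            tail[t, i] = pts[0]
            head[t, i] = pts[-1]

    frame_idx = np.repeat(np.arange(n_frames), config.n_animals)
    ids = np.tile(np.arange(config.n_animals), n_frames)
    frames = pd.DataFrame({
        "frame": frame_idx,
        "id": ids,
        "x_mm": cols_x.ravel(),
        "y_mm": cols_y.ravel(),
        "heading": cols_h.ravel(),
        "bend": cols_b.ravel(),
        "state": cols_state.ravel(),
        "visible": cols_vis.ravel(),
        "head_x_mm": head[..., 0].ravel(),
        "head_y_mm": head[..., 1].ravel(),
        "tail_x_mm": tail[..., 0].ravel(),
        "tail_y_mm": tail[..., 1].ravel(),
    })
    turns = pd.DataFrame(turn_log, columns=["id", "frame", "dtheta_deg"])
    events = pd.DataFrame(event_log, columns=["kind", "id", "id2", "start_frame",
                                              "end_frame", "x_mm", "y_mm"])
    return GroundTruth(frames=frames, turns=turns, events=events, config=config)


def _draw_disk(img: np.ndarray, cx: float, cy: float, r: float, value: float) -> None:
    h, w = img.shape
    x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, w)
    y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    region = img[y0:y1, x0:x1]
    region[mask] = np.maximum(region[mask], value)


def render_video(truth: GroundTruth, config: SimConfig | None = None):
    """Yield (frame_index, uint8 frame) for the full simulated recording.

    Each visible larva is drawn as an elongated uniformly bright blob (a
    chain of disks along the body arc, mildly tapered toward the tail, ~30 px
    at the default scale).  The background is a dark field that drifts slowly
    in intensity; occlusion gaps draw a dark robot-arm patch over the animal.
    """
    config = config or truth.config
    ppm = config.px_per_mm
    length_px = config.body_length * ppm
    if length_px < 3.0:
        raise ValueError("rendered animal smaller than 3 px; increase px_per_mm")
    h = w = int(round(config.arena_side * ppm))
    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed).spawn(2)[1])
    yy = np.linspace(0, 2 * np.pi, h)[:, None]
    xx = np.linspace(0, 2 * np.pi, w)[None, :]
    pattern = 0.25 * (2.0 + np.cos(yy) + np.sin(xx))   # smooth, in [0, 1]
    r_head = 0.60 * config.body_width * ppm
    r_tail = 0.38 * config.body_width * ppm
    n_disks = max(5, int(round(length_px)))
    # axial shift putting the tapered blob's area centroid on the true
    # position, calibrated on a rendered straight reference body
    radii = np.linspace(r_tail, r_head, n_disks)
    side = int(4 * length_px) + 8
    ref = np.zeros((side, side), dtype=np.float32)
    mid = side / 2.0
    for fx, r in zip(np.linspace(-0.5, 0.5, n_disks), radii):
        _draw_disk(ref, mid + fx * length_px, mid, r, 1.0)
    ys0, xs0 = np.nonzero(ref > 0)
    axial_shift = float(xs0.mean() + 0.0 - mid) / ppm
    groups = truth.frames.groupby("frame", sort=True)
    reloc = truth.events[truth.events["kind"] == "relocation"]

    for t, g in groups:
        drift = min(config.background_drift * t, 45.0)
        frame = np.full((h, w), config.background_level, dtype=np.float32)
        if drift > 0:
            frame += (drift * pattern).astype(np.float32)
        for row in g.itertuples(index=False):
            if not row.visible:
                continue
            cx = row.x_mm - axial_shift * np.cos(row.heading)
            cy = row.y_mm - axial_shift * np.sin(row.heading)
            pts_mm = body_polyline(cx, cy, row.heading, row.bend,
                                   config.body_length, n=n_disks)
            px, py = mm_to_px(pts_mm[:, 0], pts_mm[:, 1],
                              config.arena_side, ppm)
            for dx, dy, r in zip(px, py, radii):
                _draw_disk(frame, dx, dy, r, config.larva_intensity)
        # robot-arm patch over occluded animals
        for ev in reloc.itertuples(index=False):
            if ev.start_frame <= t < ev.end_frame:
                ex, ey = mm_to_px(ev.x_mm, ev.y_mm, config.arena_side, ppm)
                half_patch = int(3.0 * ppm)
                y0, y1 = max(int(ey) - half_patch, 0), min(int(ey) + half_patch, h)
                x0, x1 = max(int(ex) - half_patch, 0), min(int(ex) + half_patch, w)
                frame[y0:y1, x0:x1] = 3.0
        if config.noise_sd > 0:
            frame += rng.normal(0.0, config.noise_sd, size=frame.shape).astype(np.float32)
        yield int(t), np.clip(frame, 0, 255).astype(np.uint8)


def render_array(truth: GroundTruth, config: SimConfig | None = None) -> np.ndarray:
    """Render the whole video into one (T, H, W) uint8 array (small runs)."""
    frames = [f for _, f in render_video(truth, config)]
    return np.stack(frames, axis=0)


def simulate_variability(model: VariabilityModel) -> tuple[np.ndarray, np.ndarray]:
    """Draw the Gaussian variability toy model.

    Returns ``(observations, mu)`` where ``observations`` has shape
    (n_animals, n_obs_per_animal) and ``mu`` holds the latent per-animal
    means.  Animal ``i`` observes ``N(mu_i, sigma_intra^2)`` with
    ``mu_i ~ N(mu_population, sigma_inter^2)`` (optionally centred on one of
    ``mu_modes`` chosen uniformly, emulating discrete behavioral phenotypes).
    A fraction ``common_mode_frac`` of the within-animal variance is a
    temporal fluctuation shared by all animals at each timepoint, so the
    per-timepoint population mean fluctuates with the width of an
    individual's distribution rather than narrowing by sqrt(n).
    """
    rng = np.random.default_rng(model.rng_seed)
    if model.mu_modes is not None:
        centres = rng.choice(np.asarray(model.mu_modes, dtype=float),
                             size=model.n_animals)
    else:
        centres = np.full(model.n_animals, model.mu_population)
    mu = centres + model.sigma_inter * rng.standard_normal(model.n_animals)
    f = model.common_mode_frac
    shared = np.sqrt(f) * model.sigma_intra * rng.standard_normal(
        model.n_obs_per_animal)
    own = np.sqrt(1.0 - f) * model.sigma_intra * rng.standard_normal(
        (model.n_animals, model.n_obs_per_animal))
    obs = mu[:, None] + shared[None, :] + own
    return obs, mu
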