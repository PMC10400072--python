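"""End-to-end pipelines: video -> tracks/postures, tracks -> behavior and
navigation statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import behavior as bh
from . import features as ft
from . import stats as st
from .background import (extract_detections, initialize_background,
                         subtract_and_threshold, update_background)
from .config import PipelineConfig
from .linking import Tracker
from .posture import Posture, compute_spine, estimate_head_tail_geometric

__all__ = ["track_video", "analyze_tracks"]


def _make_posture_fn(posture_cfg):
    previous: dict[int, Posture] = {}

    def posture_fn(det, track):
        mom = track.momentum()
        try:
            kp = estimate_head_tail_geometric(det.contour, previous.get(track.id),
                                              mom, posture_cfg.min_momentum)
            if kp.head is None:
                raise ValueError("no keypoints")
            full = compute_spine(det.contour, kp.head, kp.tail,
                                 posture_cfg.n_spine_points)
            full.confidence = kp.confidence if kp.confidence > 0 else full.confidence
        except ValueError:
            previous.pop(track.id, None)
            return dict(head_x=np.nan, head_y=np.nan, tail_x=np.nan,
                        tail_y=np.nan, bend_deg=np.nan, midspine_x=np.nan,
                        midspine_y=np.nan, confidence=0.0)
        previous[track.id] = full
        return dict(head_x=full.head[0], head_y=full.head[1],
                    tail_x=full.tail[0], tail_y=full.tail[1],
                    bend_deg=full.body_bend, midspine_x=full.midspine[0],
                    midspine_y=full.midspine[1], confidence=full.confidence)

    return posture_fn


def track_video(frames, cfg: PipelineConfig, with_posture: bool = True,
                progress: bool = False):
    """Run background subtraction, detection, linking and posture over a
    frame stream.

    ``frames`` yields ``(frame_index, 2-D uint8 array)`` in order.  Returns
    ``(tracks_df, events_df)``: the tidy per-frame per-id table (pixel and
    mm coordinates, posture columns, interpolation/collision flags) and the
    collision-event log.
    """
    bg_cfg = cfg.background
    frames = iter(frames)
    buffered: list[tuple[int, np.ndarray]] = []
    if bg_cfg.init == "median":
        for item in frames:
            buffered.append(item)
            if len(buffered) >= bg_cfg.init_frames:
                break
        stack = np.stack([f for _, f in buffered])
        model = initialize_background(stack, bg_cfg.alpha, mode="median")
    else:
        first = next(frames)
        buffered.append(first)
        model = initialize_background(first[1], bg_cfg.alpha, mode="first")

    posture_fn = _make_posture_fn(cfg.posture) if with_posture else None
    tracker = Tracker(cfg.linking, max_animals=cfg.sim.n_animals,
                      max_single_area=bg_cfg.max_area, posture_fn=posture_fn)

    import itertools
    for t, frame in itertools.chain(buffered, frames):
        mask = subtract_and_threshold(frame, model, bg_cfg.threshold)
        model = update_background(model, frame)
        dets = extract_detections(mask, bg_cfg.min_area, 8 * bg_cfg.max_area,
                                  frame_index=t)
        tracker.step(t, dets)
        if progress and t % 500 == 0:
            print(f"frame {t}: {len(dets)} detections, "
                  f"{len(tracker._open_tracks())} open tracks")

    tracks_df = tracker.to_dataframe(arena_side=cfg.sim.arena_side,
                                     px_per_mm=cfg.sim.px_per_mm)
    ev_rows = [dict(kind="collision", start_frame=ev.start_frame,
                    end_frame=ev.last_frame, participants=str(ev.participants),
                    status=ev.status) for ev in tracker.events]
    events_df = pd.DataFrame(ev_rows, columns=["kind", "start_frame",
                                               "end_frame", "participants",
                                               "status"])
    return tracks_df, events_df


def analyze_tracks(tracks_df: pd.DataFrame, cfg: PipelineConfig):
    """Behavioral features and statistics per animal.

    Returns ``(per_frame, turn_events, report)``: the input table augmented
    with speed/state columns, the turn-event table across animals, and a
    summary dict (per-animal navigation indices, handedness, turn rates,
    stitched path lengths, and the population bimodality of per-animal
    navigation indices when enough animals are present).
    """
    if len(tracks_df) == 0:
        raise ValueError("empty tracks")
    fr = cfg.frame_rate
    fcfg = cfg.features
    out_frames = []
    all_events = []
    report: dict = {"per_animal": {}}
    has_bend = "bend_deg" in tracks_df.columns
    for tid, g in tracks_df.groupby("id"):
        g = g.sort_values("frame").reset_index(drop=True)
        if len(g) < max(cfg.behavior.min_block, 5):
            continue
        valid = ~(g["interpolated"] | g["collision"]).to_numpy()
        x, y = g["x_mm"].to_numpy(), g["y_mm"].to_numpy()
        speed = ft.compute_speed(x, y, fr, fcfg.speed_window, valid=valid)
        g["speed_mm_s"] = speed
        if has_bend:
            bend = g["bend_deg"].to_numpy()
        else:
            bend = np.zeros(len(g))
        seq = bh.classify_heuristic(bend, speed, x, y, cfg.behavior, valid=valid)
        g["state"] = np.where(seq.states == bh.TURN, "turn", "run")
        events = seq.events.copy()
        if len(events):
            events["id"] = tid
            events["onset_frame"] = g["frame"].to_numpy()[events["onset"]]
            events["offset_frame"] = g["frame"].to_numpy()[events["offset"]]
            all_events.append(events)
        hand = ft.turn_handedness(events)
        nav = ft.navigation_index(x, y, fr, axis=fcfg.gradient_axis, valid=valid)
        # relocation gaps show up as large jumps between valid frames;
        # stitch over valid frames only, breaking segments at the jumps
        vx, vy = x[valid], y[valid]
        step = np.hypot(np.diff(vx), np.diff(vy))
        breaks = (np.flatnonzero(step > 5.0) + 1).tolist()
        sx, sy, length_m = ft.stitch_trajectory(vx, vy, breaks)
        rate = len(events) / (len(g) / fr / 60.0)
        report["per_animal"][int(tid)] = dict(
            navigation_index=nav, handedness=hand.handedness,
            n_turns=int(len(events)), turn_rate_per_min=rate,
            path_length_m=length_m,
            mean_speed_mm_s=float(np.nanmean(speed)),
        )
        out_frames.append(g)
    per_frame = pd.concat(out_frames, ignore_index=True) if out_frames else tracks_df
    turn_events = (pd.concat(all_events, ignore_index=True)
                   if all_events else pd.DataFrame(
                       columns=["onset", "offset", "size_deg", "direction",
                                "id", "onset_frame", "offset_frame"]))
    navs = [v["navigation_index"] for v in report["per_animal"].values()
            if np.isfinite(v["navigation_index"])]
    report["population"] = {
        "n_animals": len(report["per_animal"]),
        "mean_navigation_index": float(np.mean(navs)) if navs else float("nan"),
    }
    if len(navs) >= 4 and np.ptp(navs) > 0:
        bc = st.bimodality_coefficient(navs)
        report["population"]["bc_navigation"] = bc.bc
        report["population"]["bc_bimodal"] = bool(bc.is_bimodal)
    return per_frame, turn_events, report


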