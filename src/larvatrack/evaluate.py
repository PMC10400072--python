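"""Ground-truth comparison helpers for the synthetic benchmarks."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import GroundTruth

__all__ = ["match_track_ids", "identity_accuracy", "collision_recovery"]


def match_track_ids(tracks_df: pd.DataFrame, truth: GroundTruth,
                    tol_mm: float = 3.0) -> dict[int, int]:
    """Map each track id to the true animal nearest at the track's birth."""
    mapping: dict[int, int] = {}
    tf = truth.frames
    for tid, g in tracks_df.groupby("id"):
        first = g.sort_values("frame").iloc[0]
        cand = tf[(tf["frame"] == first["frame"]) & tf["visible"]]
        if len(cand) == 0:
            continue
        d = np.hypot(cand["x_mm"] - first["x_mm"], cand["y_mm"] - first["y_mm"])
        k = int(np.argmin(d.to_numpy()))
        if d.to_numpy()[k] <= tol_mm:
            mapping[int(tid)] = int(cand["id"].to_numpy()[k])
    return mapping


def identity_accuracy(tracks_df: pd.DataFrame, truth: GroundTruth,
                      tol_mm: float = 3.0, skip_frames: int = 0) -> float:
    """Fraction of observed (frame, track) rows lying on their own animal.

    Each track is bound to a true animal at birth; a row counts as correct
    when the nearest visible true animal in that frame is the bound one and
    lies within ``tol_mm``.  Interpolated and in-collision rows are skipped
    (they carry estimated positions by construction), as are the first
    ``skip_frames`` frames (background warm-up).
    """
    mapping = match_track_ids(tracks_df, truth, tol_mm)
    tf = truth.frames
    by_frame = {f: g for f, g in tf[tf["visible"]].groupby("frame")}
    rows = tracks_df[~(tracks_df["interpolated"] | tracks_df["collision"])]
    rows = rows[rows["frame"] >= skip_frames]
    n_ok = n_tot = 0
    for row in rows.itertuples(index=False):
        if row.id not in mapping:
            continue
        g = by_frame.get(row.frame)
        if g is None or len(g) == 0:
            continue
        d = np.hypot(g["x_mm"].to_numpy() - row.x_mm,
                     g["y_mm"].to_numpy() - row.y_mm)
        k = int(np.argmin(d))
        n_tot += 1
        if d[k] <= tol_mm and int(g["id"].to_numpy()[k]) == mapping[row.id]:
            n_ok += 1
    return n_ok / n_tot if n_tot else float("nan")


def collision_recovery(tracks_df: pd.DataFrame, truth: GroundTruth,
                       margin_frames: int = 15, tol_mm: float = 3.0):
    """Per-collision identity outcome after separation.

    For each simulated collision event, checks ``margin_frames`` after the
    event end whether every surviving participant track still lies on its
    own (birth-assigned) animal.  Returns ``(n_preserved, n_evaluated)``.
    """
    mapping = match_track_ids(tracks_df, truth, tol_mm)
    inv = {}
    for track_id, true_id in mapping.items():
        inv.setdefault(true_id, track_id)
    tf = truth.frames
    n_ok = n_tot = 0
    for ev in truth.events[truth.events["kind"] == "collision"].itertuples():
        frame = int(ev.end_frame) + margin_frames
        if frame > tracks_df["frame"].max():
            continue
        ok = True
        evaluated = False
        for true_id in (int(ev.id), int(ev.id2)):
            track_id = inv.get(true_id)
            if track_id is None:
                continue
            row = tracks_df[(tracks_df["id"] == track_id)
                            & (tracks_df["frame"] == frame)]
            tr_row = tf[(tf["frame"] == frame) & (tf["id"] == true_id)]
            if len(row) == 0 or len(tr_row) == 0:
                continue
            evaluated = True
            d = float(np.hypot(row["x_mm"].iloc[0] - tr_row["x_mm"].iloc[0],
                               row["y_mm"].iloc[0] - tr_row["y_mm"].iloc[0]))
            if d > tol_mm:
                ok = False
        if evaluated:
            n_tot += 1
            n_ok += int(ok)
    return n_ok, n_tot
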