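"""Trajectory-level behavioral features.

All inputs are metric (mm, s, degrees, y-up coordinates).  Frames flagged
interpolated or in-collision are excluded from velocity-based averages so
that relocation gaps never inject spurious velocities.

The navigation index is ``<v_x>/<v>``: the mean velocity component along
the stimulus-gradient axis normalized by the mean speed (mean of norms).
It is +1.0 for straight crawling parallel to the gradient, -1.0
anti-parallel, and 0 for motion with no net preference; by Cauchy-Schwarz
it always lies in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TurnStatistics",
    "compute_speed",
    "compute_turn_rate",
    "compute_curvature",
    "turn_handedness",
    "navigation_index",
    "navigation_index_series",
    "stitch_trajectory",
    "perievent_average",
]


@dataclass(frozen=True)
class TurnStatistics:
    """Left/right turn counts and the handedness index.

    ``handedness = (N_left - N_right) / N_total`` over directed turns; +1.0
    means all turns were to the left, -1.0 all to the right.  Turns without
    a defined direction are excluded from the counts and reported in
    ``n_ambiguous``.
    """

    n_left: int
    n_right: int
    n_ambiguous: int = 0

    @property
    def n_total(self) -> int:
        return self.n_left + self.n_right

    @property
    def handedness(self) -> float:
        if self.n_total == 0:
            return float("nan")
        return (self.n_left - self.n_right) / self.n_total


def _velocities(x, y, valid, frame_rate: float):
    """Per-step velocity vectors using only steps between valid frames."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.ones(len(x), dtype=bool) if valid is None else np.asarray(valid, bool)
    step_ok = ok[:-1] & ok[1:]
    vx = np.diff(x) * frame_rate
    vy = np.diff(y) * frame_rate
    return vx[step_ok], vy[step_ok], step_ok


def compute_speed(x, y, frame_rate: float, window_s: float = 1.0,
                  valid=None) -> np.ndarray:
    """Smoothed speed series (mm/s), same length as the input.

    Central difference over the smoothing window: displacement between the
    frames half a window before and after, divided by the window duration.
    Frames flagged invalid never anchor a difference (result NaN there).
    """
    if window_s * frame_rate < 2.0:
        raise ValueError("window must span at least 2 frames")
    half = max(1, int(round(window_s * frame_rate / 2)))
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    ok = np.ones(n, dtype=bool) if valid is None else np.asarray(valid, bool)
    out = np.full(n, np.nan)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half, n - 1)
    anchors_ok = ok[lo] & ok[hi] & (hi > lo)
    d = np.hypot(x[hi] - x[lo], y[hi] - y[lo])
    dt = (hi - lo) / frame_rate
    with np.errstate(invalid="ignore", divide="ignore"):
        out[anchors_ok] = (d / dt)[anchors_ok]
    return out


def compute_turn_rate(event_onsets, n_frames: int, frame_rate: float,
                      window_s: float = 60.0) -> np.ndarray:
    """Sliding-window turn rate (events/min) sampled at every frame."""
    onsets = np.asarray(event_onsets, dtype=int)
    counts = np.zeros(n_frames)
    if len(onsets):
        np.add.at(counts, onsets[(onsets >= 0) & (onsets < n_frames)], 1.0)
    w = max(1, int(round(window_s * frame_rate)))
    kernel = np.ones(w)
    summed = np.convolve(counts, kernel, mode="same")
    # actual window length shrinks at the edges
    lengths = np.convolve(np.ones(n_frames), kernel, mode="same")
    return summed / lengths * frame_rate * 60.0


def compute_curvature(x, y, arc_step: float = 1.0) -> np.ndarray:
    """Signed discrete curvature (1/mm) of a path, per arc-length step.

    The path is resampled at ``arc_step`` spacing; curvature is the turning
    angle between consecutive steps divided by the step length.  Positive
    curvature matches the left-turn (counterclockwise, y-up) convention.
    """
    pts = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    seg = np.hypot(*np.diff(pts, axis=0).T)
    keep = seg > 1e-12                       # skip degenerate steps
    pts = np.concatenate([pts[:1], pts[1:][keep]])
    seg = np.hypot(*np.diff(pts, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] < 3 * arc_step:
        raise ValueError("path shorter than 3 arc steps")
    s = np.arange(0.0, cum[-1], arc_step)
    rx = np.interp(s, cum, pts[:, 0])
    ry = np.interp(s, cum, pts[:, 1])
    hx, hy = np.diff(rx), np.diff(ry)
    ang = np.arctan2(hy, hx)
    d = np.diff(ang)
    d = np.arctan2(np.sin(d), np.cos(d))
    return d / arc_step


def turn_handedness(events: pd.DataFrame) -> TurnStatistics:
    """Count turn directions and form the handedness index."""
    if len(events) == 0:
        return TurnStatistics(0, 0, 0)
    left = int((events["direction"] == "left").sum())
    right = int((events["direction"] == "right").sum())
    amb = int(len(events) - left - right)
    return TurnStatistics(left, right, amb)


def navigation_index(x, y, frame_rate: float, axis=(1.0, 0.0),
                     valid=None) -> float:
    """Whole-track navigation index ``<v . axis> / <|v|>``.

    NaN when there is no valid motion at all (undefined index).
    """
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.hypot(*ax)
    vx, vy, _ = _velocities(x, y, valid, frame_rate)
    if len(vx) == 0:
        return float("nan")
    speed = np.hypot(vx, vy)
    mean_speed = speed.mean()
    if mean_speed == 0:
        return float("nan")
    return float((vx * ax[0] + vy * ax[1]).mean() / mean_speed)


def navigation_index_series(x, y, frame_rate: float, window_s: float,
                            axis=(1.0, 0.0), valid=None) -> pd.DataFrame:
    """Per-window navigation indices (windows with no motion are NaN)."""
    n = len(x)
    w = max(2, int(round(window_s * frame_rate)))
    rows = []
    for start in range(0, n, w):
        stop = min(start + w, n)
        if stop - start < 2:
            continue
        sub_valid = None if valid is None else np.asarray(valid, bool)[start:stop]
        ni = navigation_index(np.asarray(x)[start:stop],
                              np.asarray(y)[start:stop],
                              frame_rate, axis=axis, valid=sub_valid)
        rows.append(dict(start_frame=start, end_frame=stop - 1, index=ni))
    return pd.DataFrame(rows, columns=["start_frame", "end_frame", "index"])


def stitch_trajectory(x, y, segment_breaks) -> tuple[np.ndarray, np.ndarray, float]:
    """Translate segments into one continuous path; return (x, y, length_m).

    ``segment_breaks`` lists the first frame index of each new segment
    (e.g. the drop-off frame after every relocation).  Each segment is
    translated so its first point coincides with the previous segment's
    last point — translation only, headings unchanged.  The cumulative
    path length is reported in meters.
    """
    x = np.asarray(x, dtype=float).copy()
    y = np.asarray(y, dtype=float).copy()
    breaks = sorted(int(b) for b in segment_breaks if 0 < b < len(x))
    for b in breaks:
        dx = x[b] - x[b - 1]
        dy = y[b] - y[b - 1]
        x[b:] -= dx
        y[b:] -= dy
    length_mm = float(np.hypot(np.diff(x), np.diff(y)).sum())
    return x, y, length_mm / 1000.0


def perievent_average(series: np.ndarray, event_frames, frame_rate: float,
                      before_s: float, after_s: float):
    """Event-aligned mean and SD of a series.

    Events without a full flanking window are excluded without error.
    Returns ``(lags_s, mean, sd, n_events)``; the event frame sits at lag 0.
    """
    series = np.asarray(series, dtype=float)
    nb = int(round(before_s * frame_rate))
    na = int(round(after_s * frame_rate))
    snippets = []
    for ev in np.asarray(event_frames, dtype=int):
        if ev - nb < 0 or ev + na >= len(series):
            continue
        snippets.append(series[ev - nb: ev + na + 1])
    if not snippets:
        raise ValueError("no events with sufficient flanking data")
    mat = np.vstack(snippets)
    lags = (np.arange(-nb, na + 1)) / frame_rate
    return lags, np.nanmean(mat, axis=0), np.nanstd(mat, axis=0), len(snippets)
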