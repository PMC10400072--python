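"""Run/turn behavioral-state segmentation and turn-event extraction.

Two classifiers share one output contract:

* :func:`classify_heuristic` — the deterministic default: a frame is a turn
  when the body bend exceeds a threshold while forward speed falls below a
  fraction of the animal's median run speed; blocks shorter than
  ``min_block`` frames are absorbed into their neighbors, which implements
  an explicit cost for switching behavioral states.
* :class:`larvatrack.nn.state.StateClassifierNet` — a trainable recurrent
  dense network whose per-frame probabilities are decoded through the same
  switching-penalty dynamic program (:func:`viterbi_smooth`).

Turn events are maximal contiguous turn blocks; the signed turn size is the
heading difference between the flanking runs, wrapped to (-180, 180], with
positive = left (counterclockwise in metric y-up coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import BehaviorConfig

__all__ = ["BehaviorSequence", "classify_heuristic", "viterbi_smooth",
           "merge_short_blocks", "extract_turn_events"]

RUN, TURN = 0, 1


@dataclass
class BehaviorSequence:
    """Per-frame states (0 = run, 1 = turn), probabilities, and turn events.

    ``events`` columns: onset (frame), offset (inclusive frame),
    size_deg (signed, positive = left), direction ('left'|'right'|'none').
    """

    states: np.ndarray
    probs: np.ndarray
    events: pd.DataFrame = field(default_factory=pd.DataFrame)


def _blocks(states: np.ndarray):
    """(start, end_inclusive, state) for each maximal constant block."""
    edges = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate([[0], edges])
    ends = np.concatenate([edges - 1, [len(states) - 1]])
    return [(int(s), int(e), int(states[s])) for s, e in zip(starts, ends)]


def merge_short_blocks(states: np.ndarray, min_block: int) -> np.ndarray:
    """Absorb state blocks shorter than ``min_block`` into their neighbors.

    Repeated until stable, shortest blocks first; interior blocks flip to
    the surrounding state, edge blocks to their single neighbor.  The result
    strictly alternates run and turn blocks.
    """
    out = states.astype(int).copy()
    while True:
        blocks = _blocks(out)
        if len(blocks) <= 1:
            return out
        short = [(e - s + 1, i) for i, (s, e, _) in enumerate(blocks)]
        short = [t for t in short if t[0] < min_block]
        if not short:
            return out
        _, i = min(short)
        s, e, st = blocks[i]
        out[s:e + 1] = 1 - st


def wrap_deg(a):
    """Wrap degrees to (-180, 180]."""
    return -((180.0 - np.asarray(a)) % 360.0) + 180.0


def _heading_deg(x: np.ndarray, y: np.ndarray, idx: np.ndarray) -> float:
    """Mean crawl direction (degrees, y-up metric) over the given frames."""
    if len(idx) < 2:
        return float("nan")
    dx = x[idx[-1]] - x[idx[0]]
    dy = y[idx[-1]] - y[idx[0]]
    return float(np.degrees(np.arctan2(dy, dx)))


def extract_turn_events(states: np.ndarray, x_mm: np.ndarray, y_mm: np.ndarray,
                        valid: np.ndarray | None = None,
                        flank: int = 5) -> pd.DataFrame:
    """Turn-event table from a state sequence and a metric trajectory.

    Turn size is heading(run after) - heading(run before), each heading
    estimated over up to ``flank`` valid frames of the adjacent runs; frames
    flagged invalid (interpolated / in collision) never anchor a heading.
    Events whose flanking headings are undefined get direction 'none'.
    """
    n = len(states)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    rows = []
    for s, e, st in _blocks(np.asarray(states)):
        if st != TURN:
            continue
        pre = np.flatnonzero(valid[:s])[-flank:]
        post = np.flatnonzero(valid[e + 1:])[:flank] + e + 1
        h0 = _heading_deg(x_mm, y_mm, pre) if len(pre) >= 2 else float("nan")
        h1 = _heading_deg(x_mm, y_mm, post) if len(post) >= 2 else float("nan")
        size = wrap_deg(h1 - h0) if np.isfinite(h0) and np.isfinite(h1) else float("nan")
        if np.isfinite(size) and size != 0:
            direction = "left" if size > 0 else "right"
        else:
            direction = "none"
        rows.append(dict(onset=s, offset=e, size_deg=float(size),
                         direction=direction))
    return pd.DataFrame(rows, columns=["onset", "offset", "size_deg", "direction"])


def classify_heuristic(bend_deg: np.ndarray, speed_mm_s: np.ndarray,
                       x_mm: np.ndarray, y_mm: np.ndarray,
                       cfg: BehaviorConfig = BehaviorConfig(),
                       valid: np.ndarray | None = None) -> BehaviorSequence:
    """Deterministic run/turn segmentation.

    A frame is a turn when ``|bend| > bend_threshold`` and speed falls below
    ``speed_fraction`` of the median speed over non-turn-candidate frames;
    blocks shorter than ``min_block`` are merged into their neighbors.
    """
    bend = np.nan_to_num(np.asarray(bend_deg, dtype=float))
    speed = np.asarray(speed_mm_s, dtype=float)
    n = len(bend)
    if n < cfg.min_block:
        raise ValueError("series shorter than min_block")
    finite_speed = speed[np.isfinite(speed)]
    median_speed = np.median(finite_speed) if len(finite_speed) else 0.0
    speed_thr = cfg.speed_fraction * median_speed
    slow = np.where(np.isfinite(speed), speed < speed_thr, False)
    raw = ((np.abs(bend) > cfg.bend_threshold) & slow).astype(int)
    states = merge_short_blocks(raw, cfg.min_block)
    probs = np.zeros((n, 2))
    probs[np.arange(n), states] = 1.0
    events = extract_turn_events(states, np.asarray(x_mm, dtype=float),
                                 np.asarray(y_mm, dtype=float), valid=valid)
    return BehaviorSequence(states=states, probs=probs, events=events)


def viterbi_smooth(probs: np.ndarray, switch_cost: float) -> np.ndarray:
    """Maximum-a-posteriori state path under a per-transition penalty.

    Minimizes ``sum_t -log p_t(s_t) + switch_cost * [s_t != s_{t-1}]`` by
    dynamic programming over the two states.  ``switch_cost`` 0 reduces to
    per-frame argmax; an infinite cost collapses the path to one state.
    """
    p = np.clip(np.asarray(probs, dtype=float), 1e-12, 1.0)
    emit = -np.log(p)
    n, k = emit.shape
    cost = emit[0].copy()
    back = np.zeros((n, k), dtype=int)
    for t in range(1, n):
        for s in range(k):
            trans = cost + switch_cost * (np.arange(k) != s)
            back[t, s] = int(np.argmin(trans))
            cost_s = trans[back[t, s]]
            emit[t, s] += cost_s
        cost = emit[t]
    path = np.empty(n, dtype=int)
    path[-1] = int(np.argmin(cost))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path
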