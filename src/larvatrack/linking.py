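"""Frame-to-frame identity assignment, gap interpolation, and collision
resolution.

Identities are linked by minimizing a weighted pairwise loss between each
new detection i and each existing track j::

    L_ij = beta_r * D(r_i, r_j) + beta_p * D(p_i, p_j) + beta_a * D(a_i, a_j)

where r is the centroid, p the momentum (recent displacement per frame),
a the contour area, and D the Euclidean distance.  Assignment is greedy:
the globally lowest loss is linked first, then the next lowest among the
remaining pairs, and so on — deliberately not a globally optimal matching.

When two animals collide their contours merge into a single oversized
contour.  The resolver translates each participant's pre-collision contour
mask, initialized at its momentum-predicted displacement, and hill-climbs
the translations for a bounded number of epochs so the union of translated
masks best overlaps the merged contour; the translated centroids stand in
as positions during the collision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .background import Detection
from .config import LinkingConfig

__all__ = [
    "Track",
    "CollisionEvent",
    "link_loss",
    "assign_identities",
    "interpolate_gap",
    "detect_collision",
    "resolve_collision",
    "Tracker",
]


@dataclass
class Track:
    """Identity-preserving per-animal history (pixel coordinates)."""

    id: int
    frames: list = field(default_factory=list)
    xs: list = field(default_factory=list)
    ys: list = field(default_factory=list)
    areas: list = field(default_factory=list)
    interpolated: list = field(default_factory=list)
    collision: list = field(default_factory=list)
    extras: list = field(default_factory=list)   # per-frame dicts (posture etc.)
    open: bool = True
    # raster support of the last clean (non-collision) detection
    last_mask: np.ndarray | None = None
    last_mask_offset: tuple[int, int] = (0, 0)

    @property
    def r(self) -> np.ndarray:
        return np.array([self.xs[-1], self.ys[-1]])

    @property
    def a(self) -> float:
        return self.areas[-1]

    @property
    def last_seen(self) -> int:
        return self.frames[-1]

    def momentum(self, window: int = 5) -> np.ndarray:
        """Mean displacement per frame over up to ``window`` recent steps."""
        if len(self.frames) < 2:
            return np.zeros(2)
        k = min(window, len(self.frames) - 1)
        df = self.frames[-1] - self.frames[-1 - k]
        if df <= 0:
            return np.zeros(2)
        return np.array([self.xs[-1] - self.xs[-1 - k],
                         self.ys[-1] - self.ys[-1 - k]]) / df

    def predict(self, window: int = 5) -> np.ndarray:
        return self.r + self.momentum(window)

    def append(self, frame: int, x: float, y: float, area: float,
               interpolated: bool = False, collision: bool = False,
               extra: dict | None = None) -> None:
        self.frames.append(frame)
        self.xs.append(float(x))
        self.ys.append(float(y))
        self.areas.append(float(area))
        self.interpolated.append(bool(interpolated))
        self.collision.append(bool(collision))
        self.extras.append(extra or {})


@dataclass
class CollisionEvent:
    """A span of frames where >= 2 animals share one merged contour."""

    start_frame: int
    participants: list[int]
    priors: dict                      # id -> (mask, offset) pre-collision raster
    shifts: dict                      # id -> np.ndarray current translation
    last_frame: int = -1
    status: str = "open"              # open | resolved | fallback
    resolved_positions: list = field(default_factory=list)  # (frame, id, x, y)
    det: Detection | None = None      # the merged detection that opened it


def link_loss(det: Detection, track: Track, cfg: LinkingConfig,
              momentum_window: int | None = None) -> float:
    """Weighted linking loss between a detection and a track.

    The detection's momentum is its candidate displacement from the track's
    last position.
    """
    w = momentum_window or cfg.momentum_window
    r_j, p_j, a_j = track.r, track.momentum(w), track.a
    r_i = np.asarray(det.centroid, dtype=float)
    p_i = r_i - r_j
    return float(cfg.beta_r * np.hypot(*(r_i - r_j))
                 + cfg.beta_p * np.hypot(*(p_i - p_j))
                 + cfg.beta_a * abs(det.area - a_j))


def assign_identities(dets: list[Detection], tracks: list[Track],
                      cfg: LinkingConfig):
    """Greedy lowest-loss-first matching.

    Returns ``(matches, unmatched_track_ids, unmatched_det_indices)`` where
    ``matches`` maps track id -> detection index.  Pairs with loss above
    ``cfg.max_loss`` stay unmatched.  Ties break deterministically on lower
    track id, then lower detection index.
    """
    pairs = []
    for ti, tr in enumerate(tracks):
        for di, det in enumerate(dets):
            loss = link_loss(det, tr, cfg)
            if loss <= cfg.max_loss:
                pairs.append((loss, tr.id, di, ti))
    pairs.sort()
    matches: dict[int, int] = {}
    used_tracks: set[int] = set()
    used_dets: set[int] = set()
    for loss, tid, di, ti in pairs:
        if ti in used_tracks or di in used_dets:
            continue
        matches[tid] = di
        used_tracks.add(ti)
        used_dets.add(di)
    unmatched_tracks = [tr.id for ti, tr in enumerate(tracks) if ti not in used_tracks]
    unmatched_dets = [di for di in range(len(dets)) if di not in used_dets]
    return matches, unmatched_tracks, unmatched_dets


def interpolate_gap(p0, p1, gap: int) -> np.ndarray:
    """Linearly interpolated positions across ``gap`` missing frames.

    With flanking observations at frames t and t + gap + 1, returns the
    (gap, 2) positions for frames t+1 .. t+gap; a zero-length gap is a no-op.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    if gap == 0:
        return np.empty((0, 2))
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    frac = np.arange(1, gap + 1)[:, None] / (gap + 1)
    return p0 + frac * (p1 - p0)


def _point_near_mask(point: np.ndarray, mask: np.ndarray,
                     offset: tuple[int, int], pad: float) -> bool:
    x, y = point
    x0, y0 = offset
    h, w = mask.shape
    if not (x0 - pad <= x <= x0 + w + pad and y0 - pad <= y <= y0 + h + pad):
        return False
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        return False
    d2 = (xs + x0 - x) ** 2 + (ys + y0 - y) ** 2
    return bool(d2.min() <= pad * pad)


def detect_collision(dets: list[Detection], tracks: list[Track],
                     cfg: LinkingConfig, max_single_area: float,
                     pad: float = 6.0) -> list[CollisionEvent]:
    """Open collision events: >= 2 predicted track positions inside one
    oversized detection."""
    events = []
    for det in dets:
        if det.area <= max_single_area:
            continue
        members = [tr for tr in tracks if tr.open and _point_near_mask(
            tr.predict(cfg.momentum_window), det.mask, det.offset, pad)]
        if len(members) >= 2:
            priors = {tr.id: (tr.last_mask, tr.last_mask_offset) for tr in members
                      if tr.last_mask is not None}
            shifts = {tr.id: tr.predict(cfg.momentum_window)
                      - _mask_centroid(*priors[tr.id]) for tr in members
                      if tr.id in priors}
            if len(priors) >= 2:
                events.append(CollisionEvent(start_frame=det.frame_index,
                                             participants=[tr.id for tr in members],
                                             priors=priors, shifts=shifts,
                                             det=det))
    return events


def _mask_centroid(mask: np.ndarray, offset: tuple[int, int]) -> np.ndarray:
    ys, xs = np.nonzero(mask)
    return np.array([xs.mean() + offset[0], ys.mean() + offset[1]])


def _paint(canvas: np.ndarray, mask: np.ndarray, ox: int, oy: int) -> None:
    h, w = mask.shape
    H, W = canvas.shape
    x0, y0 = max(ox, 0), max(oy, 0)
    x1, y1 = min(ox + w, W), min(oy + h, H)
    if x0 >= x1 or y0 >= y1:
        return
    canvas[y0:y1, x0:x1] |= mask[y0 - oy:y1 - oy, x0 - ox:x1 - ox]


def resolve_collision(priors: dict, init_shifts: dict, merged_mask: np.ndarray,
                      merged_offset: tuple[int, int], max_epochs: int = 50,
                      iou_floor: float = 0.25):
    """Optimize per-participant integer translations of prior contours.

    Coordinate-ascent hill climbing: each epoch proposes shifts within a
    +/-2 px neighborhood for each participant in turn, keeping the move that
    maximizes intersection-over-union between the union of translated prior
    masks and the merged contour mask.  Initial shifts come from momentum
    prediction.  Returns ``(positions, shifts, status)`` where positions maps
    id -> translated prior centroid in frame coordinates; status is
    ``resolved`` or ``fallback`` (final overlap below ``iou_floor``; momentum
    initialization is kept).
    """
    margin = 8
    mh, mw = merged_mask.shape
    W, H = mw + 2 * margin, mh + 2 * margin
    target = np.zeros((H, W), dtype=bool)
    target[margin:margin + mh, margin:margin + mw] = merged_mask
    tsum = target.sum()
    ids = list(priors)
    shifts = {i: np.round(np.asarray(init_shifts[i], dtype=float)).astype(int)
              for i in ids}

    def score(current: dict) -> float:
        union = np.zeros((H, W), dtype=bool)
        for i in ids:
            mask, (px, py) = priors[i]
            ox = px + current[i][0] - merged_offset[0] + margin
            oy = py + current[i][1] - merged_offset[1] + margin
            _paint(union, mask, ox, oy)
        inter = np.logical_and(union, target).sum()
        uni = union.sum() + tsum - inter
        return inter / uni if uni else 0.0

    best = score(shifts)
    moves = [np.array([dx, dy]) for dx in range(-2, 3) for dy in range(-2, 3)
             if (dx, dy) != (0, 0)]
    for _ in range(max_epochs):
        improved = False
        for i in ids:
            base = shifts[i].copy()
            for mv in moves:
                shifts[i] = base + mv
                s = score(shifts)
                if s > best + 1e-12:
                    best = s
                    base = shifts[i].copy()
                    improved = True
            shifts[i] = base
        if not improved:
            break
    status = "resolved" if best >= iou_floor else "fallback"
    if status == "fallback":
        shifts = {i: np.round(np.asarray(init_shifts[i], dtype=float)).astype(int)
                  for i in ids}
    positions = {i: _mask_centroid(*priors[i]) + shifts[i] for i in ids}
    return positions, shifts, status


class Tracker:
    """Streaming multi-animal tracker.

    Feed frames in order via :meth:`step`; each step runs detection
    splitting, collision bookkeeping, greedy identity assignment, gap
    interpolation, and track lifecycle management.  ``posture_fn``, when
    given, is called as ``posture_fn(det, track)`` on every clean match and
    its dict is stored with the frame.
    """

    def __init__(self, link_cfg: LinkingConfig, max_animals: int,
                 max_single_area: float, posture_fn=None):
        self.cfg = link_cfg
        self.max_animals = max_animals
        self.max_single_area = max_single_area
        self.posture_fn = posture_fn
        self.tracks: list[Track] = []
        self.events: list[CollisionEvent] = []
        self._next_id = 0

    # ------------------------------------------------------------------
    def _open_tracks(self):
        return [tr for tr in self.tracks if tr.open]

    def _in_collision_ids(self):
        out = set()
        for ev in self.events:
            if ev.status == "open":
                out.update(ev.participants)
        return out

    def step(self, frame_index: int, detections: list[Detection]) -> None:
        cfg = self.cfg
        normal = [d for d in detections if d.area <= self.max_single_area]
        oversized = [d for d in detections if d.area > self.max_single_area]
        open_tracks = self._open_tracks()
        consumed: set[int] = set()

        # ---- continue open collision events ---------------------------
        for ev in self.events:
            if ev.status != "open":
                continue
            remaining = [d for k, d in enumerate(oversized) if k not in consumed]
            det = self._matching_oversized(ev, remaining)
            if det is None:
                ev.status = "resolved"   # blob separated; participants re-enter
                continue
            consumed.add(next(k for k, d in enumerate(oversized) if d is det))
            positions, shifts, _status = resolve_collision(
                ev.priors, ev.shifts, det.mask, det.offset,
                max_epochs=cfg.max_epochs)
            ev.shifts = shifts
            ev.last_frame = frame_index
            for tr in open_tracks:
                if tr.id in positions:
                    x, y = positions[tr.id]
                    tr.append(frame_index, x, y, tr.a, collision=True)
                    ev.resolved_positions.append((frame_index, tr.id, x, y))

        busy = self._in_collision_ids()
        free_tracks = [tr for tr in open_tracks if tr.id not in busy]

        # ---- open new collision events --------------------------------
        fresh_oversized = [d for k, d in enumerate(oversized) if k not in consumed]
        new_events = detect_collision(fresh_oversized, free_tracks, cfg,
                                      self.max_single_area)
        for ev in new_events:
            ev.last_frame = frame_index
            self.events.append(ev)
            for k, d in enumerate(oversized):
                if d is ev.det:
                    consumed.add(k)
                    break
            # resolve already on the opening frame so shifts start aligned
            positions, shifts, _status = resolve_collision(
                ev.priors, ev.shifts, ev.det.mask, ev.det.offset,
                max_epochs=cfg.max_epochs)
            ev.shifts = shifts
            for tr in free_tracks:
                if tr.id in positions:
                    x, y = positions[tr.id]
                    tr.append(frame_index, x, y, tr.a, collision=True)
                    ev.resolved_positions.append((frame_index, tr.id, x, y))
        busy = self._in_collision_ids()
        free_tracks = [tr for tr in free_tracks if tr.id not in busy]

        # degenerate: an oversized blob not tied to any collision (e.g. a
        # single stretched animal) links like an ordinary detection
        for k, det in enumerate(oversized):
            if k not in consumed:
                normal.append(det)

        # ---- ordinary greedy assignment -------------------------------
        matches, unmatched_tracks, unmatched_dets = assign_identities(
            normal, free_tracks, cfg)
        by_id = {tr.id: tr for tr in free_tracks}
        for tid, di in matches.items():
            tr = by_id[tid]
            det = normal[di]
            gap = frame_index - tr.last_seen - 1
            if gap > 0:
                filled = interpolate_gap(tr.r, det.centroid, gap)
                for k, (x, y) in enumerate(filled):
                    tr.append(tr.last_seen + 1, x, y, tr.a, interpolated=True)
            extra = None
            if self.posture_fn is not None:
                extra = self.posture_fn(det, tr)
            tr.append(frame_index, det.centroid[0], det.centroid[1], det.area,
                      extra=extra)
            if det.area <= self.max_single_area:
                tr.last_mask = det.mask
                tr.last_mask_offset = det.offset

        # ---- rescue pass: long-lost tracks may re-match without the gate
        # (robot relocations drop animals far beyond max_loss)
        lost = [by_id[tid] for tid in unmatched_tracks
                if frame_index - by_id[tid].last_seen >= cfg.rescue_min_gap]
        if lost and unmatched_dets:
            pairs = []
            for tr in lost:
                for di in unmatched_dets:
                    d = np.hypot(normal[di].centroid[0] - tr.r[0],
                                 normal[di].centroid[1] - tr.r[1])
                    pairs.append((d, tr.id, di))
            pairs.sort()
            used_t, used_d = set(), set()
            for _, tid, di in pairs:
                if tid in used_t or di in used_d:
                    continue
                used_t.add(tid)
                used_d.add(di)
                tr = by_id[tid]
                det = normal[di]
                gap = frame_index - tr.last_seen - 1
                if gap > 0:
                    for x, y in interpolate_gap(tr.r, det.centroid, gap):
                        tr.append(tr.last_seen + 1, x, y, tr.a, interpolated=True)
                extra = self.posture_fn(det, tr) if self.posture_fn else None
                tr.append(frame_index, det.centroid[0], det.centroid[1],
                          det.area, extra=extra)
                tr.last_mask = det.mask
                tr.last_mask_offset = det.offset
            unmatched_tracks = [t for t in unmatched_tracks if t not in used_t]
            unmatched_dets = [d for d in unmatched_dets if d not in used_d]

        # ---- lifecycle -------------------------------------------------
        for tid in unmatched_tracks:
            tr = by_id[tid]
            if frame_index - tr.last_seen > cfg.interp_max_gap:
                tr.open = False
        n_open = len(self._open_tracks())
        for di in unmatched_dets:
            if n_open >= self.max_animals:
                break
            det = normal[di]
            if det.area > self.max_single_area:
                continue
            tr = Track(id=self._next_id)
            self._next_id += 1
            tr.append(frame_index, det.centroid[0], det.centroid[1], det.area)
            tr.last_mask = det.mask
            tr.last_mask_offset = det.offset
            self.tracks.append(tr)
            n_open += 1

    def _matching_oversized(self, ev: CollisionEvent, oversized: list[Detection]):
        """The oversized detection continuing this event, if any."""
        best, best_d = None, np.inf
        ref = np.mean([_mask_centroid(*ev.priors[i]) + ev.shifts[i]
                       for i in ev.priors], axis=0)
        for det in oversized:
            d = np.hypot(det.centroid[0] - ref[0], det.centroid[1] - ref[1])
            if d < best_d:
                best, best_d = det, d
        if best is not None and best_d < 40.0:
            return best
        return None

    # ------------------------------------------------------------------
    def to_dataframe(self, arena_side: float | None = None,
                     px_per_mm: float | None = None):
        """Flatten all tracks into a tidy table (one row per frame per id)."""
        import pandas as pd

        rows = []
        for tr in self.tracks:
            for k in range(len(tr.frames)):
                row = dict(frame=tr.frames[k], id=tr.id, x_px=tr.xs[k],
                           y_px=tr.ys[k], area=tr.areas[k],
                           interpolated=tr.interpolated[k],
                           collision=tr.collision[k])
                row.update(tr.extras[k])
                rows.append(row)
        df = pd.DataFrame(rows).sort_values(["frame", "id"]).reset_index(drop=True)
        if arena_side is not None and px_per_mm is not None and len(df):
            from .config import px_to_mm
            df["x_mm"], df["y_mm"] = px_to_mm(df["x_px"], df["y_px"],
                                              arena_side, px_per_mm)
        return df
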