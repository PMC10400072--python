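"""Posture estimation: head/tail keypoints, contour-halving spine, midspine
position, and body-bend angle.

The default, fully deterministic estimator finds the body endpoints as the
two contour points of locally maximal curvature (larval head and tail are
the sharpest features of the silhouette) and disambiguates head from tail
with the crawling direction: larvae crawl head-first during runs, so the
head is the endpoint better aligned with the track's momentum.  A learned
heatmap alternative lives in :mod:`larvatrack.nn.heatmap`.

The spine is built by splitting the contour at head and tail into two
half-contours c1 and c2, resampling both to the same number of points by
arc length, and taking midpoints of equidistant pairs; the middle spine
vertex (the "midspine") serves as a contour-noise-robust position of the
animal, and the angle between the head-half and tail-half mean directions
is the body-bend angle (0 deg = straight).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Posture", "estimate_head_tail_geometric", "compute_spine",
           "resample_polyline"]


@dataclass
class Posture:
    head: tuple[float, float] | None = None
    tail: tuple[float, float] | None = None
    confidence: float = 0.0
    spine: np.ndarray | None = None         # (n_points, 2), head -> tail
    midspine: tuple[float, float] | None = None
    body_bend: float = float("nan")         # degrees, 0 = straight


def _closed_curvature(pts: np.ndarray, k: int = 3) -> np.ndarray:
    """Turning angle at each vertex of a closed polyline, over k-step chords."""
    n = len(pts)
    prev = pts[(np.arange(n) - k) % n]
    nxt = pts[(np.arange(n) + k) % n]
    v1 = pts - prev
    v2 = nxt - pts
    a1 = np.arctan2(v1[:, 1], v1[:, 0])
    a2 = np.arctan2(v2[:, 1], v2[:, 0])
    d = a2 - a1
    return np.abs(np.arctan2(np.sin(d), np.cos(d)))


def _arc_lengths(pts: np.ndarray, closed: bool = True) -> np.ndarray:
    seg = np.diff(pts, axis=0, append=pts[:1] if closed else None)
    return np.hypot(seg[:, 0], seg[:, 1])


def estimate_head_tail_geometric(contour: np.ndarray,
                                 previous: Posture | None,
                                 momentum: np.ndarray,
                                 min_momentum: float = 0.3) -> Posture:
    """Locate head and tail on a body contour (pixel coordinates).

    Endpoints are the two local curvature maxima separated by at least a
    third of the perimeter.  The head is the endpoint whose offset from the
    other endpoint best aligns with the momentum vector; when momentum is
    below ``min_momentum`` (px/frame) the previous frame's assignment is
    kept for temporal consistency.  A near-circular contour (indistinct
    curvature extremes) yields low confidence and carries the previous
    posture through.
    """
    pts = np.asarray(contour, dtype=float)
    if len(pts) and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 8:
        raise ValueError("contour needs >= 8 vertices")
    curv = _closed_curvature(pts, k=max(2, len(pts) // 12))
    n = len(pts)
    seg = _arc_lengths(pts)
    cum = np.concatenate([[0.0], np.cumsum(seg)])[:-1]
    perim = cum[-1] + seg[-1]

    i0 = int(np.argmax(curv))
    # second endpoint: curvature max at arc distance >= perimeter / 3
    arc_d = np.abs(cum - cum[i0])
    arc_d = np.minimum(arc_d, perim - arc_d)
    far = arc_d >= perim / 3.0
    if not far.any():
        return _carry(previous)
    i1 = int(np.argmax(np.where(far, curv, -np.inf)))
    # indistinct extremes -> near-circular contour
    contrast = (curv[i0] + curv[i1]) / 2.0 - np.median(curv)
    if contrast < 0.05:
        return _carry(previous)
    e0, e1 = pts[i0], pts[i1]

    momentum = np.asarray(momentum, dtype=float)
    if np.hypot(*momentum) >= min_momentum:
        head, tail = (e0, e1) if np.dot(e0 - e1, momentum) >= 0 else (e1, e0)
    elif previous is not None and previous.head is not None:
        ph = np.asarray(previous.head)
        head, tail = (e0, e1) if (np.hypot(*(e0 - ph)) <= np.hypot(*(e1 - ph))) \
            else (e1, e0)
    else:
        head, tail = e0, e1   # arbitrary but deterministic
    conf = float(np.clip(contrast / 1.0, 0.0, 1.0))
    return Posture(head=tuple(head), tail=tuple(tail), confidence=conf)


def _carry(previous: Posture | None) -> Posture:
    if previous is None:
        return Posture(confidence=0.0)
    return Posture(head=previous.head, tail=previous.tail, confidence=0.0)


def resample_polyline(pts: np.ndarray, n: int) -> np.ndarray:
    """Resample an open polyline to n points, uniformly in arc length."""
    pts = np.asarray(pts, dtype=float)
    seg = np.hypot(*np.diff(pts, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] == 0:
        return np.repeat(pts[:1], n, axis=0)
    s = np.linspace(0.0, cum[-1], n)
    x = np.interp(s, cum, pts[:, 0])
    y = np.interp(s, cum, pts[:, 1])
    return np.column_stack([x, y])


def compute_spine(contour: np.ndarray, head, tail, n_points: int = 11) -> Posture:
    """Spine polyline, midspine, and body bend from a contour and keypoints.

    The contour is split at the vertices nearest head and tail into the two
    half-contours; both are resampled to ``n_points`` and averaged pairwise.
    ``body_bend`` is the signed angle (degrees) between the tail-half and
    head-half mean directions; positive bends the head toward the animal's
    left in metric (y-up) convention, i.e. clockwise in image coordinates.
    """
    pts = np.asarray(contour, dtype=float)
    if len(pts) and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    head = np.asarray(head, dtype=float)
    tail = np.asarray(tail, dtype=float)
    ih = int(np.argmin(np.hypot(*(pts - head).T)))
    it = int(np.argmin(np.hypot(*(pts - tail).T)))
    if ih == it:
        raise ValueError("head and tail snap to the same contour vertex")
    if ih < it:
        c1 = pts[ih:it + 1]
        c2 = np.concatenate([pts[it:], pts[:ih + 1]])[::-1]
    else:
        c1 = pts[it:ih + 1][::-1]
        c2 = np.concatenate([pts[ih:], pts[:it + 1]])
    # both run head -> tail after this; snap exact endpoints
    c1[0] = c2[0] = pts[ih]
    c1[-1] = c2[-1] = pts[it]
    r1 = resample_polyline(c1, n_points)
    r2 = resample_polyline(c2, n_points)
    spine = 0.5 * (r1 + r2)
    spine[0], spine[-1] = pts[ih], pts[it]
    mid = (n_points - 1) // 2
    midspine = spine[mid]

    head_segs = spine[:mid + 1][:-1] - spine[:mid + 1][1:]    # toward head
    tail_segs = spine[mid:][:-1] - spine[mid:][1:]            # toward midspine
    v1 = head_segs.mean(axis=0)
    v2 = tail_segs.mean(axis=0)
    dot = float(np.dot(v1, v2))
    cross = float(v2[0] * v1[1] - v2[1] * v1[0])
    # image coordinates are y-down: flip sign so positive = left (CCW, y-up)
    bend = -np.degrees(np.arctan2(cross, dot))
    return Posture(head=tuple(pts[ih]), tail=tuple(pts[it]),
                   confidence=1.0, spine=spine, midspine=tuple(midspine),
                   body_bend=float(bend))
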