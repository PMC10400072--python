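"""Dynamic background modelling and per-frame larva detection.

The background is an exponentially weighted running average of the incoming
frames (an infinite-impulse-response filter), ``B_t = alpha * F_t +
(1 - alpha) * B_{t-1}``, which adapts to slow changes such as condensation
or dust while leaving the fast-moving bright animals in the foreground.
Animals are then detected as connected clusters of bright pixels in the
background-subtracted frame, gated by a contour-area range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "BackgroundModel",
    "Detection",
    "update_background",
    "subtract_and_threshold",
    "extract_detections",
    "initialize_background",
]


@dataclass(frozen=True)
class BackgroundModel:
    """Running background estimate ``B`` with feedforward coefficient alpha."""

    B: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


@dataclass
class Detection:
    """One candidate animal in one frame.

    ``contour`` is the outermost closed polygon (N, 2) in (x, y) pixel
    coordinates; ``mask``/``offset`` carry the filled raster support used by
    the collision resolver (offset = (x0, y0) of the mask in the frame).
    """

    centroid: tuple[float, float]
    area: float
    frame_index: int
    contour: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)
    offset: tuple[int, int] = (0, 0)


def update_background(model: BackgroundModel, frame: np.ndarray) -> BackgroundModel:
    """One IIR step: ``B <- alpha * F + (1 - alpha) * B`` (pure update)."""
    F = np.asarray(frame, dtype=np.float64)
    if F.shape != model.B.shape:
        raise ValueError(f"frame shape {F.shape} != background shape {model.B.shape}")
    return BackgroundModel(B=model.alpha * F + (1.0 - model.alpha) * model.B,
                           alpha=model.alpha)


def initialize_background(frames: np.ndarray | list, alpha: float,
                          mode: str = "first") -> BackgroundModel:
    """Build the initial background from the first frame or a median stack.

    ``first`` seeds with frame 0 (animals bleed in and wash out with the
    filter); ``median`` takes a per-pixel median over the provided frames,
    which removes moving animals from the start.
    """
    stack = np.asarray(frames, dtype=np.float64)
    if mode == "first":
        B0 = stack if stack.ndim == 2 else stack[0]
    elif mode == "median":
        if stack.ndim != 3:
            raise ValueError("median initialization needs a frame stack")
        B0 = np.median(stack, axis=0)
    else:
        raise ValueError("mode must be 'first' or 'median'")
    return BackgroundModel(B=B0.copy(), alpha=alpha)


def subtract_and_threshold(frame: np.ndarray, model: BackgroundModel,
                           threshold: float) -> np.ndarray:
    """Boolean foreground mask: positive residual above a fixed offset.

    Negative residuals (frame darker than background) are clipped to zero
    before thresholding.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    residual = np.asarray(frame, dtype=np.float64) - model.B
    np.clip(residual, 0.0, None, out=residual)
    return residual > threshold


def extract_detections(mask: np.ndarray, min_area: float, max_area: float,
                       frame_index: int = 0) -> list[Detection]:
    """Connected bright clusters within the size gate, as Detections.

    Only outermost contours are considered: each component is hole-filled
    before measuring, so interior holes never split or shrink an animal.
    Area is the filled pixel count; the centroid is the mean of the filled
    pixel coordinates.
    """
    if not 0 < min_area < max_area:
        raise ValueError("require 0 < min_area < max_area")
    labels, n = ndimage.label(mask)
    if n == 0:
        return []
    detections: list[Detection] = []
    for sl, lab in zip(ndimage.find_objects(labels), range(1, n + 1)):
        if sl is None:
            continue
        comp = labels[sl] == lab
        comp = ndimage.binary_fill_holes(comp)
        area = float(comp.sum())
        if not min_area <= area <= max_area:
            continue
        ys, xs = np.nonzero(comp)
        y0, x0 = sl[0].start, sl[1].start
        # pixel-centre centroid in full-frame coordinates
        centroid = (float(xs.mean() + x0), float(ys.mean() + y0))
        padded = np.pad(comp, 1)
        cont = measure.find_contours(padded.astype(float), 0.5)
        cont = max(cont, key=len) if cont else np.empty((0, 2))
        # find_contours returns (row, col); convert to (x, y) in frame coords
        contour = np.column_stack([cont[:, 1] - 1 + x0, cont[:, 0] - 1 + y0])
        detections.append(Detection(centroid=centroid, area=area,
                                    frame_index=frame_index, contour=contour,
                                    mask=comp, offset=(x0, y0)))
    return detections
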