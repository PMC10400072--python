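"""Recurrent U-Net for head/tail keypoint heatmaps.

Encoder: four submodules of (3x3 convolution, ReLU, 2x2 max pool); decoder
mirrors them with 2x nearest upsampling and skip connections from the
corresponding encoder level.  Recurrence enters as convolutional LSTM cells
at three places — the network entry, the bottleneck, and the decoder output
— so that each frame's prediction can lean on the previous frames of the
same animal (larval posture changes little between frames, and the carried
state penalizes spurious head/tail flips).

The output is a two-channel probability heatmap (head, tail), each channel
normalized to sum to one over the crop.  Keypoints are decoded by argmax
with subpixel quadratic refinement; confidence is the probability mass in
the surrounding 5x5 window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Adam, Tensor, concat, maxpool2d, upsample2d
from .layers import Conv2d, ConvLSTMCell, Module, cross_entropy

__all__ = ["HeatmapNetConfig", "RecurrentUNet", "decode_keypoints",
           "gaussian_heatmap", "train_heatmap_network"]


@dataclass(frozen=True)
class HeatmapNetConfig:
    crop_size: int = 64
    base_channels: int = 4     # doubled at each of the four encoder levels
    depth: int = 4
    n_keypoints: int = 2       # head, tail
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.crop_size % (2 ** self.depth) != 0:
            raise ValueError("crop_size must be divisible by 2**depth")


class RecurrentUNet(Module):
    def __init__(self, cfg: HeatmapNetConfig = HeatmapNetConfig()):
        rng = np.random.default_rng(cfg.rng_seed)
        self.cfg = cfg
        ch = [cfg.base_channels * 2 ** i for i in range(cfg.depth)]
        self.entry_lstm = ConvLSTMCell(1, ch[0], 3, rng)
        self.enc = [Conv2d(ch[max(i - 1, 0)] if i else ch[0], ch[i], 3, rng)
                    for i in range(cfg.depth)]
        self.bottleneck_lstm = ConvLSTMCell(ch[-1], ch[-1], 3, rng)
        # decoder level i consumes upsampled deeper features + skip
        self.dec = [Conv2d(ch[i] + (ch[i + 1] if i + 1 < cfg.depth else ch[-1]),
                           ch[i], 3, rng)
                    for i in reversed(range(cfg.depth))]
        self.out_lstm = ConvLSTMCell(ch[0], ch[0], 3, rng)
        self.head = Conv2d(ch[0], cfg.n_keypoints, 3, rng)

    def __call__(self, crop: np.ndarray | Tensor) -> Tensor:
        """One 64x64 crop (or batch) -> (N, K, H, W) probability maps."""
        x = crop if isinstance(crop, Tensor) else Tensor(
            np.asarray(crop, dtype=float))
        if x.data.ndim == 2:
            x = x.reshape(1, 1, *x.data.shape)
        elif x.data.ndim == 3:
            x = x.reshape(x.data.shape[0], 1, *x.data.shape[1:])
        x = self.entry_lstm(x)
        skips = []
        for conv in self.enc:
            x = conv(x).relu()
            skips.append(x)
            x = maxpool2d(x)
        x = self.bottleneck_lstm(x)
        for conv, skip in zip(self.dec, reversed(skips)):
            x = upsample2d(x)
            x = conv(concat([x, skip], axis=1)).relu()
        x = self.out_lstm(x)
        logits = self.head(x)
        n, k, h, w = logits.data.shape
        flat = logits.reshape(n, k, h * w)
        shifted = flat - Tensor(flat.data.max(axis=-1, keepdims=True))
        e = shifted.exp()
        probs = e / e.sum(axis=-1, keepdims=True)
        return probs.reshape(n, k, h, w)


def gaussian_heatmap(size: int, x: float, y: float, sigma: float = 2.0) -> np.ndarray:
    """Unit-mass Gaussian target map centred on (x, y) pixel coordinates."""
    yy, xx = np.mgrid[0:size, 0:size]
    m = np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma ** 2))
    return m / m.sum()


def decode_keypoints(prob_map: np.ndarray):
    """Per-channel argmax with quadratic subpixel refinement.

    Returns a list of ``(x, y, confidence)``; confidence is the probability
    mass inside the 5x5 window around the peak.
    """
    out = []
    for ch in prob_map:
        iy, ix = np.unravel_index(np.argmax(ch), ch.shape)
        x, y = float(ix), float(iy)
        # 1-D quadratic fit along each axis
        if 0 < ix < ch.shape[1] - 1:
            l, c, r = ch[iy, ix - 1], ch[iy, ix], ch[iy, ix + 1]
            denom = l - 2 * c + r
            if denom < 0:
                x += 0.5 * (l - r) / denom
        if 0 < iy < ch.shape[0] - 1:
            u, c, d = ch[iy - 1, ix], ch[iy, ix], ch[iy + 1, ix]
            denom = u - 2 * c + d
            if denom < 0:
                y += 0.5 * (u - d) / denom
        y0, y1 = max(iy - 2, 0), min(iy + 3, ch.shape[0])
        x0, x1 = max(ix - 2, 0), min(ix + 3, ch.shape[1])
        conf = float(ch[y0:y1, x0:x1].sum())
        out.append((x, y, conf))
    return out


def train_heatmap_network(net: RecurrentUNet, crops: np.ndarray,
                          keypoints: np.ndarray, epochs: int = 3,
                          lr: float = 3e-3, sigma: float = 2.0) -> list[float]:
    """Smoke-scale training loop on labelled crops.

    ``crops``: (T, H, W) grayscale in [0, 1]; ``keypoints``: (T, K, 2) pixel
    (x, y) targets.  Frames are treated as one temporal sequence (recurrent
    state carried within an epoch, reset between epochs).  Returns the
    per-epoch mean losses.
    """
    size = net.cfg.crop_size
    targets = np.stack([
        np.stack([gaussian_heatmap(size, kx, ky, sigma) for kx, ky in frame])
        for frame in keypoints])
    opt = Adam(net.parameters(), lr=lr)
    losses = []
    for _ in range(epochs):
        net.reset_state()
        total = 0.0
        for crop, target in zip(crops, targets):
            opt.zero_grad()
            probs = net(crop[None])
            loss = cross_entropy(probs, target[None])
            loss.backward()
            opt.step()
            # detach recurrent state so the tape does not grow unbounded
            _detach_state(net)
            total += float(loss.data)
        losses.append(total / len(crops))
    return losses


def _detach_state(module: Module) -> None:
    for v in vars(module).values():
        if isinstance(v, ConvLSTMCell):
            if v._h is not None:
                v._h = Tensor(v._h.data.copy())
                v._c = Tensor(v._c.data.copy())
        elif isinstance(v, Module):
            _detach_state(v)
        elif isinstance(v, (list, tuple)):
            for item in v:
                if isinstance(item, Module):
                    _detach_state(item)
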