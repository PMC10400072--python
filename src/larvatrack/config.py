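"""Configuration objects for simulation, tracking, and analysis.

All geometry is metric (mm, s, degrees) unless a field name carries a px
suffix.  Pixel coordinates follow image convention: origin at the top-left
corner, x rightward, y downward; metric coordinates are y-up with the origin
at the bottom-left corner of the arena.  Conversion between the two is
handled by :func:`mm_to_px` / :func:`px_to_mm`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

__all__ = [
    "SimConfig",
    "VariabilityModel",
    "BackgroundConfig",
    "LinkingConfig",
    "PostureConfig",
    "BehaviorConfig",
    "FeatureConfig",
    "PipelineConfig",
    "mm_to_px",
    "px_to_mm",
]


def _require_finite(obj: Any) -> None:
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, (int, float)) and not math.isfinite(v):
            raise ValueError(f"{type(obj).__name__}.{f.name} must be finite, got {v!r}")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic larva arena.

    Defaults emulate the recorded experiments this toolkit targets: a handful
    of second-instar larvae (~1.4 mm long, rendered as ~30 bright pixels)
    crawling on a 22 x 22 cm agar arena imaged at 10 Hz from a ~2 MP camera
    (~7 px/mm), with occasional robot pick-up occlusions and rare pairwise
    collisions.
    """

    n_animals: int = 6
    arena_side: float = 220.0          # mm
    px_per_mm: float = 7.0
    frame_rate: float = 10.0           # Hz
    duration: float = 600.0            # s
    mean_speed: float = 0.5            # mm/s, crawl speed during runs
    speed_decay: float = 0.0           # mm/s^2, linear drift of the mean speed
    turn_rate: float = 3.0             # events/min during runs
    turn_size_mean: float = 60.0       # deg, magnitude of heading change per turn
    turn_size_dispersion: float = 30.0  # deg, SD of the wrapped-normal magnitude
    turn_duration: float = 1.5         # s, pause length of a turn event
    handedness_bias: float = 0.0       # in [-1, 1]; P(left) = (1 + bias) / 2
    gradient_bias: float = 0.0         # >= 0; strength of post-turn bias toward +x
    heading_jitter_sd: float = 2.0     # deg/frame von Mises heading diffusion in runs
    collision_rate: float = 0.63       # events/h, arena-wide pairwise crossings
    collision_duration: float = 4.0    # s, span of an engineered crossing
    occlusion_rate: float = 0.87       # events/h per animal (robot pick-up)
    occlusion_duration: float = 4.5    # s, camera blocked per pick-up
    relocate_on_occlusion: bool = True  # teleport to arena centre after the gap
    edge_mode: str = "reflect"         # "reflect" | "relocate"
    body_length: float = 1.4           # mm
    body_width: float = 0.4            # mm
    larva_intensity: float = 180.0     # rendered peak intensity (uint8 scale)
    background_level: float = 10.0     # base background intensity
    noise_sd: float = 0.0              # additive Gaussian noise, intensity units
    background_drift: float = 0.0      # intensity units/frame of slow drift
    rng_seed: int = 0

    def __post_init__(self) -> None:
        _require_finite(self)
        for name in (
            "arena_side", "px_per_mm", "frame_rate", "duration", "mean_speed",
            "turn_rate", "turn_size_dispersion", "turn_duration",
            "collision_rate", "occlusion_rate", "occlusion_duration",
            "gradient_bias", "heading_jitter_sd", "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"SimConfig.{name} must be non-negative")
        if not -1.0 <= self.handedness_bias <= 1.0:
            raise ValueError("handedness_bias must lie in [-1, 1]")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.edge_mode not in ("reflect", "relocate"):
            raise ValueError("edge_mode must be 'reflect' or 'relocate'")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    @property
    def frame_shape(self) -> tuple[int, int]:
        side = int(round(self.arena_side * self.px_per_mm))
        return (side, side)


@dataclass(frozen=True)
class VariabilityModel:
    """Gaussian toy model of intra- vs inter-animal variability.

    Animal ``i`` receives a latent mean ``mu_i ~ N(mu_population,
    sigma_inter^2)``; its observations are ``N(mu_i, sigma_intra^2)``.
    """

    n_animals: int = 8
    n_obs_per_animal: int = 500
    mu_population: float = 0.0
    sigma_intra: float = 0.3
    sigma_inter: float = 0.05
    #: optional modes for a mixture placement of the per-animal means
    #: (e.g. (-0.2, 0.45) reproduces a strong/neutral crawler dichotomy);
    #: when set, each animal's mean is a randomly chosen mode plus
    #: N(0, sigma_inter^2) and mu_population is ignored.
    mu_modes: tuple[float, ...] | None = None
    #: fraction of the within-animal variance that is a population-shared
    #: temporal fluctuation (animals in one arena co-fluctuate with the
    #: environment); the remainder is independent per-animal noise.  With a
    #: dominant shared component the per-timepoint population-mean density
    #: keeps the width of the individual densities instead of narrowing by
    #: sqrt(n_animals).
    common_mode_frac: float = 0.9
    rng_seed: int = 0

    def __post_init__(self) -> None:
        _require_finite(self)
        if self.sigma_intra < 0 or self.sigma_inter < 0:
            raise ValueError("sigmas must be non-negative")
        if not 0.0 <= self.common_mode_frac <= 1.0:
            raise ValueError("common_mode_frac must lie in [0, 1]")
        if self.n_animals < 2 or self.n_obs_per_animal < 2:
            raise ValueError("counts must be >= 2")


@dataclass(frozen=True)
class BackgroundConfig:
    alpha: float = 0.01          # IIR feedforward coefficient at 10 Hz
    threshold: float = 50.0      # fixed intensity offset above background
    init: str = "first"          # "first" | "median"
    init_frames: int = 100       # frames used for median initialization
                                 # (~10 s at 10 Hz: a slow larva clears its
                                 # own body length, so the median excludes it)
    min_area: float = 8.0        # px^2 size gate
    max_area: float = 45.0       # px^2 size gate: upper edge of the single-
                                 # animal blob band, so merged animals are
                                 # flagged oversized rather than linked

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if not 0 < self.min_area < self.max_area:
            raise ValueError("require 0 < min_area < max_area")
        if self.init not in ("first", "median"):
            raise ValueError("init must be 'first' or 'median'")


@dataclass(frozen=True)
class LinkingConfig:
    beta_r: float = 1.0     # weight on centroid distance (px)
    beta_p: float = 0.5     # weight on momentum distance (px/frame)
    beta_a: float = 0.01    # weight on area difference (px^2)
    max_loss: float = 60.0  # assignment gate
    interp_max_gap: int = 75   # frames; gaps beyond this close the track
    momentum_window: int = 5   # frames averaged into the momentum estimate
    max_epochs: int = 50       # collision-resolution optimization budget
    rescue_min_gap: int = 5    # frames lost before gate-free re-matching
                               # (covers robot relocations far from the gate)

    def __post_init__(self) -> None:
        if min(self.beta_r, self.beta_p, self.beta_a) < 0:
            raise ValueError("beta weights must be non-negative")
        if self.beta_r == self.beta_p == self.beta_a == 0:
            raise ValueError("at least one beta weight must be positive")


@dataclass(frozen=True)
class PostureConfig:
    crop_size: int = 64       # px, side of the per-animal crop
    n_spine_points: int = 11  # odd, so a unique midspine vertex exists
    min_momentum: float = 0.3  # px/frame below which head/tail carries over

    def __post_init__(self) -> None:
        if self.n_spine_points < 3 or self.n_spine_points % 2 == 0:
            raise ValueError("n_spine_points must be odd and >= 3")


@dataclass(frozen=True)
class BehaviorConfig:
    bend_threshold: float = 20.0    # deg
    speed_fraction: float = 0.4     # turn if speed < fraction * median run speed
    min_block: int = 3              # frames; shorter state blocks are merged
    switch_cost: float = 2.0        # -log penalty per state transition


@dataclass(frozen=True)
class FeatureConfig:
    speed_window: float = 1.0       # s
    turn_rate_window: float = 60.0  # s
    nav_index_window: float = 600.0  # s; whole-track index always reported too
    curvature_step: float = 1.0     # mm of arc per curvature sample
    gradient_axis: tuple[float, float] = (1.0, 0.0)  # +x toward the warm side


@dataclass(frozen=True)
class PipelineConfig:
    """Bundle of all stage configurations plus run-level metadata."""

    sim: SimConfig = field(default_factory=SimConfig)
    background: BackgroundConfig = field(default_factory=BackgroundConfig)
    linking: LinkingConfig = field(default_factory=LinkingConfig)
    posture: PostureConfig = field(default_factory=PostureConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    seed: int = 0

    @property
    def px_per_mm(self) -> float:
        return self.sim.px_per_mm

    @property
    def frame_rate(self) -> float:
        return self.sim.frame_rate


def mm_to_px(x_mm, y_mm, arena_side: float, px_per_mm: float):
    """Metric (y-up) to pixel (y-down) coordinates."""
    import numpy as np

    x_px = np.asarray(x_mm) * px_per_mm
    y_px = (arena_side - np.asarray(y_mm)) * px_per_mm
    return x_px, y_px


def px_to_mm(x_px, y_px, arena_side: float, px_per_mm: float):
    """Pixel (y-down) to metric (y-up) coordinates."""
    import numpy as np

    x_mm = np.asarray(x_px) / px_per_mm
    y_mm = arena_side - np.asarray(y_px) / px_per_mm
    return x_mm, y_mm


_CONFIG_CLASSES = {
    "sim": SimConfig,
    "background": BackgroundConfig,
    "linking": LinkingConfig,
    "posture": PostureConfig,
    "behavior": BehaviorConfig,
    "features": FeatureConfig,
}


def config_to_dict(cfg: PipelineConfig) -> dict:
    return dataclasses.asdict(cfg)


def config_from_dict(data: dict) -> PipelineConfig:
    """Strict construction: unknown keys at any level are rejected."""
    data = dict(data)
    kwargs: dict[str, Any] = {}
    for key, cls in _CONFIG_CLASSES.items():
        sub = data.pop(key, None)
        if sub is None:
            continue
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(sub) - known
        if unknown:
            raise KeyError(f"unknown {key} config keys: {sorted(unknown)}")
        if "gradient_axis" in sub:  # YAML lists -> tuple
            sub = {**sub, "gradient_axis": tuple(sub["gradient_axis"])}
        kwargs[key] = cls(**sub)
    if "seed" in data:
        kwargs["seed"] = int(data.pop("seed"))
    if data:
        raise KeyError(f"unknown config sections: {sorted(data)}")
    return PipelineConfig(**kwargs)
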