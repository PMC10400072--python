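"""Shared fixtures: parametric contour builders and small arena configs."""

from __future__ import annotations

import numpy as np
import pytest

from larvatrack.config import PipelineConfig, SimConfig, BackgroundConfig


def tube_contour(center: np.ndarray, w: float, n_cap: int = 11) -> np.ndarray:
    """Closed contour of a tube of half-width ``w`` around an open
    centerline, with round end caps (apex vertices included)."""
    c = np.asarray(center, float)
    d = np.gradient(c, axis=0)
    d /= np.hypot(*d.T)[:, None]
    nrm = np.column_stack([-d[:, 1], d[:, 0]])
    side1 = c + w * nrm
    side2 = (c - w * nrm)[::-1]

    def cap(pt, n0):
        angs = np.linspace(0, np.pi, n_cap)[1:-1]
        a0 = np.arctan2(n0[1], n0[0])
        return np.column_stack([pt[0] + w * np.cos(a0 - angs),
                                pt[1] + w * np.sin(a0 - angs)])

    return np.vstack([side1, cap(c[-1], nrm[-1]), side2, cap(c[0], -nrm[0])])


def ellipse_contour(cx=50.0, cy=50.0, a=12.0, b=4.0, n=200) -> np.ndarray:
    th = np.linspace(0, 2 * np.pi, n + 1)[:-1]
    return np.column_stack([cx + a * np.cos(th), cy + b * np.sin(th)])


@pytest.fixture
def quiet_sim() -> SimConfig:
    """Small deterministic arena: no events, no noise, no drift."""
    return SimConfig(n_animals=2, arena_side=40.0, duration=30.0,
                     collision_rate=0.0, occlusion_rate=0.0,
                     noise_sd=0.0, background_drift=0.0, rng_seed=7)


@pytest.fixture
def small_pipeline(quiet_sim) -> PipelineConfig:
    return PipelineConfig(sim=quiet_sim,
                          background=BackgroundConfig(init="median"))
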