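"""Distribution-level statistics for navigation behavior.

Central quantity: Sarle's bimodality coefficient

    BC = (g1^2 + 1) / (g2 + 3 (n-1)^2 / ((n-2)(n-3)))

with bias-corrected sample skewness g1 and excess kurtosis g2.  Under this
finite-sample-corrected convention the large-sample value for a uniform
distribution is 5/9, which serves as the critical value BC_crit: samples
with BC above 5/9 are flagged as possibly bimodal (a Gaussian gives 1/3).

The intra-/inter-animal decomposition contrasts two densities built from
the same observation matrix: the mean of the per-animal densities (what a
typical individual does) versus the density of per-timepoint population
means (what the averaged population does).  High inter-animal variability
with clustered individual means produces a multimodal mean-of-intra
density even though every individual stays unimodal — the dissociation
that population averages mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "BC_CRIT",
    "BimodalityResult",
    "bimodality_coefficient",
    "VariabilityDecomposition",
    "intra_inter_decomposition",
    "two_sample_t",
    "series_correlation",
]

BC_CRIT = 5.0 / 9.0


@dataclass(frozen=True)
class BimodalityResult:
    bc: float
    skewness: float
    excess_kurtosis: float
    n: int

    @property
    def is_bimodal(self) -> bool:
        return self.bc > BC_CRIT


def bimodality_coefficient(sample) -> BimodalityResult:
    """Sarle's bimodality coefficient of a 1-D sample (n >= 4 required)."""
    x = np.asarray(sample, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 4:
        raise ValueError("bimodality coefficient needs n >= 4")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance sample")
    g1 = float(sps.skew(x, bias=False))
    g2 = float(sps.kurtosis(x, fisher=True, bias=False))
    denom = g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    return BimodalityResult(bc=(g1 ** 2 + 1.0) / denom, skewness=g1,
                            excess_kurtosis=g2, n=n)


def _kde(values: np.ndarray, grid: np.ndarray, bw_floor: float) -> np.ndarray:
    """Gaussian kernel density on a grid with a Silverman bandwidth and a
    floor (keeps near-constant samples well-defined)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = len(v)
    sd = v.std(ddof=1) if n > 1 else 0.0
    h = max(1.06 * sd * n ** (-1 / 5) if sd > 0 else 0.0, bw_floor)
    dens = np.exp(-0.5 * ((grid[:, None] - v[None, :]) / h) ** 2).sum(axis=1)
    dens /= n * h * np.sqrt(2 * np.pi)
    return dens


@dataclass
class VariabilityDecomposition:
    grid: np.ndarray
    per_animal: np.ndarray          # (n_animals, grid) densities
    mean_of_intra: np.ndarray       # average of the per-animal densities
    population: np.ndarray          # density of per-timepoint cross-animal means
    intra_sd: float                 # mean of per-animal SDs
    inter_sd: float                 # SD of per-animal means
    animal_means: np.ndarray


def intra_inter_decomposition(obs: np.ndarray, grid: np.ndarray | None = None,
                              bw_floor: float = 0.01) -> VariabilityDecomposition:
    """Decompose an (animals x observations) matrix into intra/inter parts."""
    obs = np.asarray(obs, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need >= 2 animals with >= 2 observations each")
    if grid is None:
        lo, hi = obs.min(), obs.max()
        pad = 0.25 * (hi - lo + 1e-9)
        grid = np.linspace(lo - pad, hi + pad, 512)
    per_animal = np.vstack([_kde(row, grid, bw_floor) for row in obs])
    mean_of_intra = per_animal.mean(axis=0)
    pop_means = obs.mean(axis=0)          # cross-animal mean at each timepoint
    population = _kde(pop_means, grid, bw_floor)
    animal_means = obs.mean(axis=1)
    return VariabilityDecomposition(
        grid=grid, per_animal=per_animal, mean_of_intra=mean_of_intra,
        population=population,
        intra_sd=float(obs.std(axis=1, ddof=1).mean()),
        inter_sd=float(animal_means.std(ddof=1)),
        animal_means=animal_means,
    )


def two_sample_t(sample_a, sample_b, welch: bool = False):
    """Two-sample t-test (pooled variance by default) with Cohen's d.

    Returns ``(t, p, cohens_d)``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 in each sample")
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    if var_a == 0 and var_b == 0 and a.mean() == b.mean():
        return 0.0, 1.0, 0.0
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    pooled = np.sqrt(((len(a) - 1) * var_a + (len(b) - 1) * var_b)
                     / (len(a) + len(b) - 2))
    d = (a.mean() - b.mean()) / pooled if pooled > 0 else np.inf
    return float(t), float(p), float(d)


def series_correlation(series_a, series_b) -> float:
    """Pearson correlation of two aligned series, NaN pairs excluded."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("series must be equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need >= 3 aligned finite pairs")
    if np.ptp(a[ok]) == 0 or np.ptp(b[ok]) == 0:
        raise ValueError("constant series")
    return float(sps.pearsonr(a[ok], b[ok])[0])
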