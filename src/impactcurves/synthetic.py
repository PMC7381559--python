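"""Seeded generators for invader population trajectories and lake landscapes.

Real *Dreissena* populations fluctuate strongly: year-to-year variation in
biomass of roughly an order of magnitude is typical of well-studied
populations such as the Hudson River's. The trajectory generator emulates
that statistical structure with a stationary lognormal AR(1) process —
log-biomass follows a first-order autoregression, so the series is positive,
multiplicatively variable, and mildly persistent. The default preset
(25 years, log-scale SD 0.6, lag-1 autocorrelation 0.3) is calibrated so the
median max/min ratio within a series is ~10.

Landscape generation assigns ecosystem types to lakes by exact
largest-remainder rounding of the requested proportions and gives every lake
an independent trajectory whose seed derives deterministically from the
master seed and the lake index.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .shell_hash import ProductionSeries

__all__ = [
    "TrajectoryParams",
    "LandscapeSpec",
    "RealizedLandscape",
    "HUDSON_LIKE",
    "generate_trajectory",
    "generate_landscape",
    "assign_type_counts",
    "lake_rng",
]


@dataclass(frozen=True)
class TrajectoryParams:
    """Lognormal AR(1) trajectory parameters.

    ``mean_level`` is the median of the lognormal marginal (the exponential
    of the log-scale mean); ``log_sd`` is the stationary SD on the natural-log
    scale; ``autocorr`` the lag-1 autocorrelation of the log series.
    """

    n_years: int = 25
    mean_level: float = 1.0
    log_sd: float = 0.6
    autocorr: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if self.mean_level <= 0:
            raise ValueError("mean_level must be positive")
        if self.log_sd < 0:
            raise ValueError("log_sd must be non-negative")
        if not (0 <= self.autocorr < 1):
            raise ValueError("autocorr must lie in [0, 1)")


#: Preset mimicking a moderately variable riverine mussel population:
#: interannual max/min ratio of order 10 over a 25-yr record.
HUDSON_LIKE = TrajectoryParams(n_years=25, mean_level=1.0, log_sd=0.6, autocorr=0.3)


def generate_trajectory(
    params: TrajectoryParams, rng: np.random.Generator | None = None
) -> ProductionSeries:
    """Draw one seeded lognormal AR(1) series on an annual grid (years 0..n-1).

    The log series starts in its stationary distribution, so there is no
    initial transient; identical parameters and seed reproduce the series
    exactly.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    mu = np.log(params.mean_level)
    sd, rho = params.log_sd, params.autocorr
    x = np.empty(params.n_years)
    x[0] = mu + rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - rho * rho)
    eps = rng.normal(0.0, innov_sd, size=params.n_years)
    for t in range(1, params.n_years):
        x[t] = mu + rho * (x[t - 1] - mu) + eps[t]
    return ProductionSeries(np.arange(params.n_years, dtype=float), np.exp(x))


def assign_type_counts(proportions: Sequence[float], n_lakes: int) -> np.ndarray:
    """Largest-remainder apportionment of ``n_lakes`` among types.

    Each type gets floor(p*n); leftover lakes go to the largest fractional
    remainders (ties broken by type order). Counts always sum to n_lakes.
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise ValueError("proportions must be non-negative")
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError(f"proportions must sum to 1, got {p.sum()!r}")
    if n_lakes < 1:
        raise ValueError("need at least one lake")
    quotas = p * n_lakes
    counts = np.floor(quotas).astype(int)
    short = n_lakes - counts.sum()
    if short > 0:
        remainders = quotas - counts
        # stable sort keeps type order on ties
        order = np.argsort(-remainders, kind="stable")
        counts[order[:short]] += 1
    return counts


def lake_rng(master_seed: int, lake_index: int) -> np.random.Generator:
    """Deterministic per-lake generator derived from (master seed, index)."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), int(lake_index)]))


@dataclass(frozen=True)
class LandscapeSpec:
    """Composition of a landscape of lakes for the generator.

    ``trajectory`` may be a single TrajectoryParams shared by all types or a
    sequence with one entry per type (e.g. to give different ecosystem types
    different characteristic abundance levels).
    """

    type_slopes: tuple[float, ...]
    type_proportions: tuple[float, ...]
    n_lakes: int
    trajectory: TrajectoryParams | tuple[TrajectoryParams, ...] = HUDSON_LIKE

    def __post_init__(self) -> None:
        if len(self.type_slopes) != len(self.type_proportions):
            raise ValueError("one proportion per type slope required")
        traj = self.trajectory
        if isinstance(traj, (tuple, list)) and len(traj) != len(self.type_slopes):
            raise ValueError("per-type trajectory list must match the number of types")

    def trajectory_for(self, type_index: int) -> TrajectoryParams:
        if isinstance(self.trajectory, (tuple, list)):
            return self.trajectory[type_index]
        return self.trajectory


@dataclass(frozen=True)
class RealizedLandscape:
    """Concrete landscape: a type index and abundance trajectory per lake."""

    type_indices: np.ndarray
    trajectories: tuple[ProductionSeries, ...]
    spec: LandscapeSpec

    @property
    def n_lakes(self) -> int:
        return int(self.type_indices.size)


def generate_landscape(
    spec: LandscapeSpec, seed: int, n_years: int | None = None
) -> RealizedLandscape:
    """Realize a landscape: exact type counts, independent seeded trajectories.

    ``n_years`` overrides the trajectory length (useful for long-term-mean
    sampling without touching the spec).
    """
    counts = assign_type_counts(spec.type_proportions, spec.n_lakes)
    type_indices = np.repeat(np.arange(counts.size), counts)
    trajectories = []
    for lake, ti in enumerate(type_indices):
        params = spec.trajectory_for(int(ti))
        if n_years is not None:
            params = replace(params, n_years=n_years)
        trajectories.append(generate_trajectory(params, rng=lake_rng(seed, lake)))
    return RealizedLandscape(type_indices, tuple(trajectories), spec)
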