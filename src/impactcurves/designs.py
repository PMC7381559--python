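"""Three non-interchangeable formulations of the abundance-impact curve.

An abundance-impact curve plots a non-native population's total impact
against its abundance. Its points can come from three distinct sampling
designs:

- **within-system**: one ecosystem observed (or manipulated) at different
  invader abundances — the curve that actually predicts what happens in that
  ecosystem if abundance changes;
- **cross-system snapshot**: one visit to each of many ecosystems
  (space-for-time substitution);
- **cross-system long-term**: long-term mean abundance and mean impact per
  ecosystem.

When ecosystem types differ in their within-system response, the two
cross-system curves are artifacts of landscape composition and sampling: a
pooled regression through a snapshot sample need not match any within-system
curve in slope, shape — or even sign. And when the within-system response is
nonlinear, averaging abundance before applying the response differs from
averaging the impacts (Jensen's inequality), so the long-term curve also
departs from the snapshot curve.

This module builds all three curve kinds from synthetic landscapes, fits
pooled regressions the way a field analyst would, and reports the
discrepancies.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .synthetic import (
    LandscapeSpec,
    TrajectoryParams,
    generate_landscape,
)

__all__ = [
    "CurveKind",
    "AbundanceImpactCurve",
    "EcosystemType",
    "Landscape",
    "CurveFit",
    "PerCapitaEffects",
    "DesignComparison",
    "within_system_curve",
    "snapshot_sample",
    "even_snapshot",
    "long_term_sample",
    "fit_linear",
    "per_capita_effects",
    "compare_designs",
]


class CurveKind(str, enum.Enum):
    """Which sampling design produced the points — never interchangeable."""

    WITHIN_SYSTEM = "within_system"
    SNAPSHOT = "snapshot"
    LONG_TERM = "long_term"


@dataclass(frozen=True)
class AbundanceImpactCurve:
    """Ordered (abundance, impact) points with their design kind attached."""

    abundance: np.ndarray
    impact: np.ndarray
    kind: CurveKind
    source_label: str = ""
    lake_ids: np.ndarray | None = field(default=None, compare=False)
    type_indices: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.abundance, dtype=float)
        i = np.asarray(self.impact, dtype=float)
        if a.shape != i.shape or a.ndim != 1:
            raise ValueError("abundance and impact must be matching 1-d arrays")
        if np.any(a < 0):
            raise ValueError("abundances must be non-negative")
        object.__setattr__(self, "abundance", a)
        object.__setattr__(self, "impact", i)

    def __len__(self) -> int:
        return int(self.abundance.size)


@dataclass(frozen=True)
class EcosystemType:
    """One ecosystem type's within-system abundance-impact response.

    The default response is linear through the origin (zero invader, zero
    impact) with the given slope; pass ``response`` to model a nonlinear
    within-system curve (the slope is then ignored by :meth:`impact_at`).
    """

    slope: float
    label: str = ""
    response: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")

    def impact_at(self, abundance):
        a = np.asarray(abundance, dtype=float)
        if self.response is not None:
            return np.asarray(self.response(a), dtype=float)
        return self.slope * a


@dataclass(frozen=True)
class Landscape:
    """A landscape of lakes: ecosystem types in proportions, with dynamics.

    ``trajectory`` is either one TrajectoryParams shared by every lake or a
    per-type sequence, letting different ecosystem types run at different
    characteristic abundances.
    """

    types: tuple[EcosystemType, ...]
    proportions: tuple[float, ...]
    n_lakes: int
    trajectory: TrajectoryParams | tuple[TrajectoryParams, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.types) == 0:
            raise ValueError("landscape needs at least one ecosystem type")
        if self.trajectory is None:
            object.__setattr__(self, "trajectory", TrajectoryParams())
        if len(self.proportions) != len(self.types):
            raise ValueError("one proportion per ecosystem type required")
        if self.n_lakes < 1:
            raise ValueError("n_lakes must be >= 1")

    def to_spec(self) -> LandscapeSpec:
        traj = self.trajectory
        if isinstance(traj, (tuple, list)):
            traj = tuple(traj)
        return LandscapeSpec(
            type_slopes=tuple(t.slope for t in self.types),
            type_proportions=tuple(self.proportions),
            n_lakes=self.n_lakes,
            trajectory=traj,
        )


@dataclass(frozen=True)
class CurveFit:
    """Unconstrained OLS line through a curve's points."""

    slope: float
    intercept: float
    r_squared: float


def within_system_curve(
    etype: EcosystemType, abundances: Sequence[float]
) -> AbundanceImpactCurve:
    """Evaluate one ecosystem type's own response over an abundance range."""
    a = np.asarray(abundances, dtype=float)
    return AbundanceImpactCurve(
        abundance=a,
        impact=etype.impact_at(a),
        kind=CurveKind.WITHIN_SYSTEM,
        source_label=etype.label,
    )


def _curve_from_lakes(landscape, type_indices, abundances, kind, label):
    impacts = np.array(
        [
            landscape.types[ti].impact_at(a)
            for ti, a in zip(type_indices, abundances)
        ]
    )
    return AbundanceImpactCurve(
        abundance=np.asarray(abundances, dtype=float),
        impact=impacts,
        kind=kind,
        source_label=label,
        lake_ids=np.arange(len(abundances)),
        type_indices=np.asarray(type_indices),
    )


def snapshot_sample(landscape: Landscape, seed: int) -> AbundanceImpactCurve:
    """One random-year visit per lake (space-for-time substitution).

    Each lake contributes the abundance observed in one uniformly chosen
    year of its trajectory and the impact its own within-system response
    assigns to that abundance. Fully reproducible under ``seed``.
    """
    realized = generate_landscape(landscape.to_spec(), seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2**20]))
    abundances = []
    for series in realized.trajectories:
        year = rng.integers(0, len(series))
        abundances.append(series.values[year])
    return _curve_from_lakes(
        landscape, realized.type_indices, abundances, CurveKind.SNAPSHOT, "snapshot"
    )


def even_snapshot(landscape: Landscape, max_abundance: float = 10.0) -> AbundanceImpactCurve:
    """Deterministic snapshot with evenly spaced abundances within each type.

    The lakes of each type are observed at abundances evenly spaced over
    (0, max_abundance] — the idealized survey in which every ecosystem type
    is sampled across the full abundance range.
    """
    counts = generate_landscape(landscape.to_spec(), seed=0).type_indices
    type_indices, abundances = [], []
    for ti in range(len(landscape.types)):
        n_t = int(np.sum(counts == ti))
        if n_t == 0:
            continue
        grid = max_abundance * np.arange(1, n_t + 1) / n_t
        type_indices.extend([ti] * n_t)
        abundances.extend(grid)
    return _curve_from_lakes(
        landscape, type_indices, abundances, CurveKind.SNAPSHOT, "even snapshot"
    )


def long_term_sample(
    landscape: Landscape, n_years: int, seed: int
) -> AbundanceImpactCurve:
    """Long-term mean abundance vs long-term mean impact, one point per lake.

    Impact is averaged year by year through each lake's own response, so for
    a nonlinear response the mean impact differs from the response evaluated
    at the mean abundance — the Jensen gap that separates long-term from
    snapshot curves.
    """
    if n_years < 2:
        raise ValueError("long-term means need n_years >= 2")
    realized = generate_landscape(landscape.to_spec(), seed, n_years=n_years)
    mean_abund, mean_impact = [], []
    for ti, series in zip(realized.type_indices, realized.trajectories):
        etype = landscape.types[ti]
        mean_abund.append(series.values.mean())
        mean_impact.append(etype.impact_at(series.values).mean())
    curve = AbundanceImpactCurve(
        abundance=np.asarray(mean_abund),
        impact=np.asarray(mean_impact),
        kind=CurveKind.LONG_TERM,
        source_label="long-term means",
        lake_ids=np.arange(realized.n_lakes),
        type_indices=realized.type_indices,
    )
    return curve


def fit_linear(curve: AbundanceImpactCurve) -> CurveFit:
    """Unconstrained OLS through all points, as a field analyst would fit."""
    a, y = curve.abundance, curve.impact
    if np.unique(a).size < 2:
        raise ValueError("need at least 2 distinct abundances to fit a line")
    res = stats.linregress(a, y)
    return CurveFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


@dataclass(frozen=True)
class PerCapitaEffects:
    """Average (impact/abundance) and marginal (local slope) per-capita effect.

    The two coincide only for a linear through-origin curve; on a saturating
    curve the marginal effect falls below the average at high abundance.
    ``average`` is NaN with ``average_defined=False`` at zero abundance.
    """

    average: float
    marginal: float
    average_defined: bool


def per_capita_effects(curve: AbundanceImpactCurve, abundance: float) -> PerCapitaEffects:
    """Evaluate both per-capita effect measures at one abundance.

    The curve is interpolated linearly between its points; the marginal
    effect is a centered finite difference on that interpolant (one-sided at
    the range ends).
    """
    order = np.argsort(curve.abundance)
    a, y = curve.abundance[order], curve.impact[order]
    lo, hi = a[0], a[-1]
    if not (lo <= abundance <= hi):
        raise ValueError(f"abundance {abundance} outside observed range [{lo}, {hi}]")
    interp = lambda x: np.interp(x, a, y)
    if abundance > 0:
        average = float(interp(abundance) / abundance)
        defined = True
    else:
        average, defined = float("nan"), False
    span = hi - lo
    h = max(span * 1e-4, 1e-9)
    left = max(abundance - h, lo)
    right = min(abundance + h, hi)
    marginal = float((interp(right) - interp(left)) / (right - left))
    return PerCapitaEffects(average=average, marginal=marginal, average_defined=defined)


@dataclass(frozen=True)
class DesignComparison:
    """Side-by-side report of the three curve formulations for one landscape.

    ``*_sign_agrees`` flags whether the pooled cross-system slope has the
    same sign as every within-system slope; ``*_prediction_mae`` is the mean
    absolute error of the pooled line against each type's own response over
    the observed abundance range — how badly the cross-system curve would
    mispredict a within-system abundance change.
    """

    within_slopes: tuple[float, ...]
    snapshot_curve: AbundanceImpactCurve
    long_term_curve: AbundanceImpactCurve
    snapshot_fit: CurveFit
    long_term_fit: CurveFit
    snapshot_sign_agrees: bool
    long_term_sign_agrees: bool
    snapshot_prediction_mae: tuple[float, ...]
    long_term_prediction_mae: tuple[float, ...]


def _sign_agrees(pooled_slope: float, within_slopes: Sequence[float]) -> bool:
    return all(np.sign(pooled_slope) == np.sign(s) for s in within_slopes)


def _prediction_mae(fit: CurveFit, landscape: Landscape, curve: AbundanceImpactCurve):
    grid = np.linspace(curve.abundance.min(), curve.abundance.max(), 101)
    pooled = fit.slope * grid + fit.intercept
    return tuple(
        float(np.mean(np.abs(pooled - t.impact_at(grid)))) for t in landscape.types
    )


def compare_designs(
    landscape: Landscape, seed: int, n_years: int | None = None
) -> DesignComparison:
    """Build snapshot and long-term curves from one landscape and fit both.

    With a single ecosystem type and a linear response, all three slopes
    agree; mixed landscapes generally produce pooled cross-system slopes that
    match no within-system slope and can even reverse its sign.
    """
    if n_years is None:
        traj = landscape.trajectory
        n_years = (traj[0] if isinstance(traj, (tuple, list)) else traj).n_years
    snap = snapshot_sample(landscape, seed)
    long_term = long_term_sample(landscape, max(n_years, 2), seed)
    snap_fit = fit_linear(snap)
    lt_fit = fit_linear(long_term)
    within = tuple(t.slope for t in landscape.types)
    return DesignComparison(
        within_slopes=within,
        snapshot_curve=snap,
        long_term_curve=long_term,
        snapshot_fit=snap_fit,
        long_term_fit=lt_fit,
        snapshot_sign_agrees=_sign_agrees(snap_fit.slope, within),
        long_term_sign_agrees=_sign_agrees(lt_fit.slope, within),
        snapshot_prediction_mae=_prediction_mae(snap_fit, landscape, snap),
        long_term_prediction_mae=_prediction_mae(lt_fit, landscape, long_term),
    )
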