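"""Instantaneous macrophyte-habitat impact of suspension-feeder filtration.

Chains four empirical/geometric relationships to map mussel population
filtration rate (DFR, % of the water column filtered per day) to the gain in
lake-bottom area colonizable by submersed macrophytes:

1. chlorophyll response: chl_post = f_r*chl_pre + f_l*chl_pre*exp(-c*DFR),
   with a refractory fraction f_r = 0.2 of phytoplankton biomass beyond the
   reach of filtration, a labile fraction f_l = 0.8 removed exponentially,
   and decay coefficient c = 0.0347 per (%/day);
2. water clarity: log10(Secchi depth) = -0.473*log10(chl) + 0.803
   (Secchi in m, chl in ug/L) — the classical eutrophication regression;
3. light: extinction coefficient eta = 1.7/Secchi (per m, Beer-Lambert), and
   macrophytes survive down to the depth receiving 5% of surface light,
   z* = -ln(0.05)/eta;
4. bathymetry: the hypsographic curve converts z* into the fraction of lake
   plan area shallower than z*.

Impact is the increase of that colonizable area fraction over the
uninvaded (DFR = 0) baseline. The chain is instantaneous — the light climate
tracks filtration with no invasion-history dependence — so the shape of the
abundance-impact curve is set entirely by lake geometry and productivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .designs import AbundanceImpactCurve, CurveKind

__all__ = [
    "ChlResponseParams",
    "SecchiModel",
    "LightModel",
    "Bathymetry",
    "LakeScenario",
    "chl_post",
    "secchi_from_chl",
    "extinction_from_secchi",
    "colonization_depth",
    "colonizable_fraction",
    "habitat_gain_curve",
    "habitat_chain_table",
    "DEFAULT_DFR_GRID",
]

#: Default filtration-rate grid, % of water column per day.
DEFAULT_DFR_GRID = np.arange(0.0, 101.0, 1.0)


@dataclass(frozen=True)
class ChlResponseParams:
    """Phytoplankton (chlorophyll a) response to population filtration.

    refractory_fraction + labile_fraction must equal 1; the refractory part
    is the chlorophyll floor that persists at unbounded filtration.
    """

    refractory_fraction: float = 0.2
    labile_fraction: float = 0.8
    decay_coeff: float = 0.0347  # per (% of water column / day)

    def __post_init__(self) -> None:
        if min(self.refractory_fraction, self.labile_fraction, self.decay_coeff) < 0:
            raise ValueError("chlorophyll-response parameters must be non-negative")
        if not math.isclose(self.refractory_fraction + self.labile_fraction, 1.0, abs_tol=1e-12):
            raise ValueError("refractory_fraction + labile_fraction must equal 1")


@dataclass(frozen=True)
class SecchiModel:
    """log-log regression of Secchi depth (m) on chlorophyll (ug/L)."""

    slope: float = -0.473
    intercept: float = 0.803

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("Secchi slope must be negative (clarity falls with chlorophyll)")


@dataclass(frozen=True)
class LightModel:
    """Secchi-to-extinction conversion and the macrophyte light criterion."""

    secchi_extinction_product: float = 1.7
    survival_light_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.secchi_extinction_product <= 0:
            raise ValueError("secchi_extinction_product must be positive")
        if not (0 < self.survival_light_fraction <= 1):
            raise ValueError("survival_light_fraction must lie in (0, 1]")


class Bathymetry:
    """Hypsographic curve: cumulative plan-area fraction shallower than depth z.

    Three kinds:

    - ``conical``: circular cone, fraction(z) = 1 - (1 - z/max_depth)^2,
      scale-free in z/max_depth;
    - ``shelf``: piecewise-linear curve concentrating ``shelf_area_fraction``
      of the plan area between ``shelf_top`` and ``shelf_bottom``, the
      remainder split over the shallower and deeper spans in proportion to
      their depth extents;
    - ``tabulated``: user-supplied (depth, fraction) knots, linearly
      interpolated; must be non-decreasing from 0 at the surface to 1 at
      max_depth.
    """

    def __init__(
        self,
        kind: str,
        max_depth: float,
        *,
        shelf_top: float = 2.5,
        shelf_bottom: float = 3.0,
        shelf_area_fraction: float = 0.5,
        depths: np.ndarray | None = None,
        fractions: np.ndarray | None = None,
    ) -> None:
        if max_depth <= 0:
            raise ValueError("max_depth must be positive")
        self.kind = kind
        self.max_depth = float(max_depth)
        if kind == "conical":
            pass
        elif kind == "shelf":
            if not (0 < shelf_top < shelf_bottom < max_depth):
                raise ValueError("need 0 < shelf_top < shelf_bottom < max_depth")
            if not (0 < shelf_area_fraction < 1):
                raise ValueError("shelf_area_fraction must lie in (0, 1)")
            self.shelf_top = float(shelf_top)
            self.shelf_bottom = float(shelf_bottom)
            self.shelf_area_fraction = float(shelf_area_fraction)
            rest = 1.0 - shelf_area_fraction
            span_above = shelf_top
            span_below = max_depth - shelf_bottom
            self._above = rest * span_above / (span_above + span_below)
            self._below = rest - self._above
        elif kind == "tabulated":
            d = np.asarray(depths, dtype=float)
            f = np.asarray(fractions, dtype=float)
            if d.ndim != 1 or d.shape != f.shape or d.size < 2:
                raise ValueError("tabulated bathymetry needs matching depth/fraction arrays")
            if np.any(np.diff(d) <= 0) or np.any(np.diff(f) < 0):
                raise ValueError("depths must increase and fractions be non-decreasing")
            if d[0] != 0 or not math.isclose(f[0], 0.0) or not math.isclose(f[-1], 1.0):
                raise ValueError("tabulated curve must run from (0, 0) to (max_depth, 1)")
            if not math.isclose(d[-1], max_depth):
                raise ValueError("last tabulated depth must equal max_depth")
            self._depths = d
            self._fractions = f
        else:
            raise ValueError(f"unknown bathymetry kind {kind!r}")

    def shallower_area_fraction(self, z: float) -> float:
        """Fraction of lake plan area with bottom depth <= z (clips at 1)."""
        if z < 0:
            raise ValueError("depth must be non-negative")
        z = min(z, self.max_depth)
        if self.kind == "conical":
            return 1.0 - (1.0 - z / self.max_depth) ** 2
        if self.kind == "shelf":
            if z <= self.shelf_top:
                return self._above * z / self.shelf_top
            if z <= self.shelf_bottom:
                return self._above + self.shelf_area_fraction * (z - self.shelf_top) / (
                    self.shelf_bottom - self.shelf_top
                )
            return (
                self._above
                + self.shelf_area_fraction
                + self._below * (z - self.shelf_bottom) / (self.max_depth - self.shelf_bottom)
            )
        return float(np.interp(z, self._depths, self._fractions))

    @classmethod
    def conical(cls, max_depth: float) -> "Bathymetry":
        return cls("conical", max_depth)

    @classmethod
    def shelf(
        cls,
        max_depth: float = 15.0,
        shelf_top: float = 2.5,
        shelf_bottom: float = 3.0,
        shelf_area_fraction: float = 0.5,
    ) -> "Bathymetry":
        return cls(
            "shelf",
            max_depth,
            shelf_top=shelf_top,
            shelf_bottom=shelf_bottom,
            shelf_area_fraction=shelf_area_fraction,
        )


@dataclass(frozen=True)
class LakeScenario:
    """One model lake: geometry, pre-invasion productivity, and coefficients."""

    bathymetry: Bathymetry
    chl_pre: float  # ug/L
    response: ChlResponseParams = field(default_factory=ChlResponseParams)
    secchi: SecchiModel = field(default_factory=SecchiModel)
    light: LightModel = field(default_factory=LightModel)
    label: str = ""

    def __post_init__(self) -> None:
        if self.chl_pre <= 0:
            raise ValueError("pre-invasion chlorophyll must be positive")


def chl_post(chl_pre: float, dfr: float, params: ChlResponseParams | None = None) -> float:
    """Post-invasion chlorophyll (ug/L) at population filtration rate ``dfr``.

    Strictly decreasing in dfr, floored at refractory_fraction * chl_pre.
    """
    params = params or ChlResponseParams()
    if chl_pre <= 0:
        raise ValueError("chl_pre must be positive")
    if dfr < 0:
        raise ValueError("filtration rate must be non-negative")
    return chl_pre * (
        params.refractory_fraction
        + params.labile_fraction * math.exp(-params.decay_coeff * dfr)
    )


def secchi_from_chl(chl: float, model: SecchiModel | None = None) -> float:
    """Secchi depth (m) from chlorophyll (ug/L) via the log-log regression."""
    model = model or SecchiModel()
    if chl <= 0:
        raise ValueError("chlorophyll must be positive")
    return 10.0 ** (model.slope * math.log10(chl) + model.intercept)


def extinction_from_secchi(secchi: float, model: LightModel | None = None) -> float:
    """Light extinction coefficient eta (per m) = product / Secchi depth."""
    model = model or LightModel()
    if secchi <= 0:
        raise ValueError("Secchi depth must be positive")
    return model.secchi_extinction_product / secchi


def colonization_depth(eta: float, model: LightModel | None = None) -> float:
    """Depth (m) receiving the survival light fraction: z* = -ln(f)/eta."""
    model = model or LightModel()
    if eta <= 0:
        raise ValueError("extinction coefficient must be positive")
    return -math.log(model.survival_light_fraction) / eta


def colonizable_fraction(bath: Bathymetry, z: float) -> float:
    """Plan-area fraction of lake bottom shallower than the lighted depth z."""
    return bath.shallower_area_fraction(z)


def _depth_at_dfr(lake: LakeScenario, dfr: float) -> float:
    c = chl_post(lake.chl_pre, dfr, lake.response)
    s = secchi_from_chl(c, lake.secchi)
    eta = extinction_from_secchi(s, lake.light)
    return colonization_depth(eta, lake.light)


def habitat_gain_curve(
    lake: LakeScenario, dfr_grid: np.ndarray | None = None
) -> AbundanceImpactCurve:
    """Habitat gain (colonizable-area fraction above the DFR=0 baseline) vs DFR.

    If the uninvaded lake is already lighted to the bottom (baseline
    colonization depth >= max depth), the curve is identically zero at every
    filtration rate — invasion cannot brighten a bottom that is already
    fully lit.
    """
    grid = DEFAULT_DFR_GRID if dfr_grid is None else np.asarray(dfr_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("dfr grid must be non-empty")
    if np.any(grid < 0):
        raise ValueError("filtration rates must be non-negative")
    base = colonizable_fraction(lake.bathymetry, _depth_at_dfr(lake, 0.0))
    gains = np.array(
        [colonizable_fraction(lake.bathymetry, _depth_at_dfr(lake, d)) - base for d in grid]
    )
    return AbundanceImpactCurve(
        abundance=grid,
        impact=gains,
        kind=CurveKind.WITHIN_SYSTEM,
        source_label=lake.label or "habitat gain",
    )


def habitat_chain_table(lake: LakeScenario, dfr_grid: np.ndarray | None = None):
    """Full intermediate table of the filtration-to-habitat chain.

    Returns a pandas DataFrame with columns dfr, chl_post, secchi_m,
    eta_per_m, z_star_m, colonizable_fraction, gain.
    """
    import pandas as pd

    grid = DEFAULT_DFR_GRID if dfr_grid is None else np.asarray(dfr_grid, dtype=float)
    rows = []
    base = colonizable_fraction(lake.bathymetry, _depth_at_dfr(lake, 0.0))
    for d in grid:
        c = chl_post(lake.chl_pre, d, lake.response)
        s = secchi_from_chl(c, lake.secchi)
        eta = extinction_from_secchi(s, lake.light)
        z = colonization_depth(eta, lake.light)
        f = colonizable_fraction(lake.bathymetry, z)
        rows.append(
            {
                "dfr": d,
                "chl_post": c,
                "secchi_m": s,
                "eta_per_m": eta,
                "z_star_m": z,
                "colonizable_fraction": f,
                "gain": f - base,
            }
        )
    return pd.DataFrame(rows)
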