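"""CSV reading/writing for production series, trajectories, and curve tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .designs import AbundanceImpactCurve, CurveFit
from .shell_hash import CouplingResult, ProductionSeries, ShellTrajectory

__all__ = [
    "load_production_csv",
    "write_production_csv",
    "write_trajectory_csv",
    "write_coupling_csv",
    "write_points_csv",
    "write_fits_csv",
]


def load_production_csv(path: str | Path) -> ProductionSeries:
    """Read a two-column (year, production_kg_m2_yr) CSV into a series.

    Validates strictly increasing years and non-negative production, naming
    the offending row (1-based, excluding the header) in any error.
    """
    df = pd.read_csv(path)
    required = ["year", "production_kg_m2_yr"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; expected {required}")
    years = df["year"].to_numpy(dtype=float)
    values = df["production_kg_m2_yr"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(years) <= 0)
    if bad.size:
        raise ValueError(
            f"{path}: years must be strictly increasing; violation at data row {bad[0] + 2}"
        )
    neg = np.flatnonzero(values < 0)
    if neg.size:
        raise ValueError(f"{path}: negative production at data row {neg[0] + 1}")
    nan = np.flatnonzero(~np.isfinite(values) | ~np.isfinite(years))
    if nan.size:
        raise ValueError(f"{path}: non-numeric entry at data row {nan[0] + 1}")
    return ProductionSeries(years, values)


def write_production_csv(series: ProductionSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"year": series.times, "production_kg_m2_yr": series.values}
    ).to_csv(path, index=False)


def write_trajectory_csv(traj: ShellTrajectory, path: str | Path) -> None:
    """Write (year, production, stock) rows; production at the final mark is
    blank because no interval starts there."""
    prod = np.append(traj.production, np.nan)
    pd.DataFrame(
        {"year": traj.times, "production": prod, "stock": traj.stock}
    ).to_csv(path, index=False)


def write_coupling_csv(result: CouplingResult, path: str | Path) -> None:
    pd.DataFrame(
        {"year": result.years, "production": result.production, "stock": result.stock}
    ).to_csv(path, index=False)


def write_points_csv(curves: list[AbundanceImpactCurve], path: str | Path) -> None:
    frames = []
    for curve in curves:
        n = len(curve)
        frames.append(
            pd.DataFrame(
                {
                    "lake_id": curve.lake_ids if curve.lake_ids is not None else np.arange(n),
                    "type": curve.type_indices if curve.type_indices is not None else 0,
                    "abundance": curve.abundance,
                    "impact": curve.impact,
                    "design_kind": curve.kind.value,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_fits_csv(fits: dict[str, CurveFit], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "design_kind": kind,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
            }
            for kind, fit in fits.items()
        ]
    ).to_csv(path, index=False)
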