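"""Reproducible experiment runner: config validation, stage execution, manifest.

A run is a stage name ("shell", "macrophyte", or "designs"), a block of
stage-specific options, an output directory, and a seed. Every run writes its
tables as CSV plus a ``manifest.json`` recording the stage, the fully
resolved options, the seed, and the package version — enough to re-run the
stage exactly. Identical config and seed give identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .designs import (
    CurveKind,
    EcosystemType,
    Landscape,
    compare_designs,
    even_snapshot,
    fit_linear,
)
from .habitat import Bathymetry, LakeScenario, habitat_chain_table
from .io import (
    load_production_csv,
    write_coupling_csv,
    write_fits_csv,
    write_points_csv,
    write_trajectory_csv,
)
from .presets import PRESETS
from .shell_hash import ShellParams, production_stock_coupling, simulate_stock
from .synthetic import HUDSON_LIKE, TrajectoryParams, generate_trajectory

__all__ = ["RunConfig", "run_stage", "load_config"]

log = logging.getLogger("impactcurves")

STAGES = ("shell", "macrophyte", "designs")


@dataclass(frozen=True)
class RunConfig:
    stage: str
    options: dict = field(default_factory=dict)
    out_dir: Path = Path("runs")
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        object.__setattr__(self, "out_dir", Path(self.out_dir))


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run config with keys stage/options/out_dir/seed/log_level."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}; expected {sorted(known)}")
    if "stage" not in raw:
        raise ValueError(f"{path}: missing required key 'stage'")
    return RunConfig(**raw)


def resolve_preset(stage: str, name: str) -> dict:
    try:
        return dict(PRESETS[stage][name])
    except KeyError:
        raise ValueError(
            f"unknown {stage} preset {name!r}; available: {sorted(PRESETS[stage])}"
        ) from None


def _check_options(stage: str, options: dict, allowed: set[str]) -> None:
    unknown = set(options) - allowed
    if unknown:
        raise ValueError(
            f"{stage} stage: unknown option key(s) {sorted(unknown)}; expected subset of {sorted(allowed)}"
        )


def _manifest(config: RunConfig, options: dict, outputs: list[str]) -> None:
    config.out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": config.stage,
        "options": options,
        "seed": config.seed,
        "package_version": __version__,
        "outputs": outputs,
    }
    with open(config.out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def _run_shell(config: RunConfig) -> list[str]:
    opts = dict(config.options)
    _check_options(
        "shell",
        opts,
        {"k_per_year", "s0", "years", "production", "production_csv", "trajectory"},
    )
    if "k_per_year" not in opts:
        raise ValueError("shell stage: missing required option key 'k_per_year'")
    params = ShellParams(k=float(opts["k_per_year"]))
    s0 = float(opts.get("s0", 0.0))
    years = int(opts.get("years", 130))
    if "production_csv" in opts:
        series = load_production_csv(opts["production_csv"])
    elif "production" in opts:
        from .shell_hash import ProductionSeries

        series = ProductionSeries.constant(float(opts["production"]), years)
    else:
        traj_opts = dict(opts.get("trajectory") or {})
        traj = dataclasses.replace(
            HUDSON_LIKE, n_years=years, seed=config.seed, **traj_opts
        )
        series = generate_trajectory(traj)
    trajectory = simulate_stock(series, params, s0=s0)
    outputs = ["trajectory.csv"]
    config.out_dir.mkdir(parents=True, exist_ok=True)
    write_trajectory_csv(trajectory, config.out_dir / "trajectory.csv")
    # coupling diagnostic only when the series survives the burn-in
    burn_in = max(5.0 / params.k, 10.0)
    if np.ptp(series.values) > 0 and (series.times[-1] - series.times[0]) >= burn_in + 5:
        coupling = production_stock_coupling(series, params, s0=s0)
        write_coupling_csv(coupling, config.out_dir / "coupling.csv")
        with open(config.out_dir / "coupling_summary.json", "w") as fh:
            json.dump(
                {
                    "pearson_r": coupling.correlation,
                    "p_value": coupling.p_value,
                    "defined": coupling.defined,
                    "burn_in_years": coupling.burn_in_years,
                },
                fh,
                indent=2,
            )
        outputs += ["coupling.csv", "coupling_summary.json"]
    return outputs


def _run_macrophyte(config: RunConfig) -> list[str]:
    opts = dict(config.options)
    _check_options("macrophyte", opts, {"bathymetry", "chl_pre", "dfr_grid", "response", "secchi", "light"})
    if "bathymetry" not in opts or "chl_pre" not in opts:
        missing = [k for k in ("bathymetry", "chl_pre") if k not in opts]
        raise ValueError(f"macrophyte stage: missing required option key(s) {missing}")
    bath_opts = dict(opts["bathymetry"])
    kind = bath_opts.pop("kind")
    max_depth = bath_opts.pop("max_depth")
    bath = Bathymetry(kind, max_depth, **bath_opts)
    extra = {}
    if "response" in opts:
        from .habitat import ChlResponseParams

        extra["response"] = ChlResponseParams(**opts["response"])
    if "secchi" in opts:
        from .habitat import SecchiModel

        extra["secchi"] = SecchiModel(**opts["secchi"])
    if "light" in opts:
        from .habitat import LightModel

        extra["light"] = LightModel(**opts["light"])
    lake = LakeScenario(bathymetry=bath, chl_pre=float(opts["chl_pre"]), **extra)
    grid = None
    if "dfr_grid" in opts:
        g = opts["dfr_grid"]
        grid = np.arange(g.get("start", 0.0), g.get("stop", 100.0) + g.get("step", 1.0) / 2, g.get("step", 1.0))
    table = habitat_chain_table(lake, grid)
    config.out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(config.out_dir / "habitat.csv", index=False)
    return ["habitat.csv"]


def _run_designs(config: RunConfig) -> list[str]:
    opts = dict(config.options)
    _check_options(
        "designs",
        opts,
        {"slopes", "labels", "proportions", "n_lakes", "trajectory", "n_years", "abundance_mode", "max_abundance"},
    )
    if "slopes" not in opts:
        raise ValueError("designs stage: missing required option key 'slopes'")
    slopes = list(opts["slopes"])
    labels = list(opts.get("labels", [f"type{i}" for i in range(len(slopes))]))
    proportions = tuple(opts.get("proportions", [1 / len(slopes)] * len(slopes)))
    traj = dataclasses.replace(HUDSON_LIKE, **dict(opts.get("trajectory") or {}))
    landscape = Landscape(
        types=tuple(EcosystemType(s, label=l) for s, l in zip(slopes, labels)),
        proportions=proportions,
        n_lakes=int(opts.get("n_lakes", 30)),
        trajectory=traj,
    )
    mode = opts.get("abundance_mode", "trajectory")
    config.out_dir.mkdir(parents=True, exist_ok=True)
    if mode == "even":
        snap = even_snapshot(landscape, max_abundance=float(opts.get("max_abundance", 10.0)))
        fits = {"snapshot": fit_linear(snap)}
        write_points_csv([snap], config.out_dir / "points.csv")
    elif mode == "trajectory":
        report = compare_designs(landscape, seed=config.seed, n_years=opts.get("n_years"))
        fits = {
            CurveKind.SNAPSHOT.value: report.snapshot_fit,
            CurveKind.LONG_TERM.value: report.long_term_fit,
        }
        write_points_csv(
            [report.snapshot_curve, report.long_term_curve], config.out_dir / "points.csv"
        )
    else:
        raise ValueError(f"designs stage: unknown abundance_mode {mode!r}")
    write_fits_csv(fits, config.out_dir / "fits.csv")
    return ["points.csv", "fits.csv"]


_RUNNERS = {"shell": _run_shell, "macrophyte": _run_macrophyte, "designs": _run_designs}


def run_stage(config: RunConfig, preset: str | None = None) -> list[Path]:
    """Execute one stage, write its CSV outputs and manifest, return paths.

    ``preset`` merges a named canonical scenario under the explicit options
    (explicit keys win).
    """
    logging.basicConfig(level=config.log_level)
    options = dict(config.options)
    if preset is not None:
        options = {**resolve_preset(config.stage, preset), **options}
        config = dataclasses.replace(config, options=options)
    log.info("running stage %s with seed %d -> %s", config.stage, config.seed, config.out_dir)
    outputs = _RUNNERS[config.stage](config)
    _manifest(config, options, outputs)
    return [config.out_dir / name for name in outputs + ["manifest.json"]]
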