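# impactcurves

Simulation models showing that a single invasive species does not have one
abundance–impact curve: the invaded ecosystem co-determines the curve's
slope, shape, and dynamics. The package is built around the invasive
suspension-feeding mussel *Dreissena* (zebra/quagga mussels), whose two
best-understood impacts bracket the problem:

- **Cumulative impact — shell accumulation** (`impactcurves.shell_hash`).
  Dead-shell standing stock *S* (kg/m²) obeys *dS/dt = P − kS*, with shell
  production *P* the abundance metric and *k* (1/yr) the ecosystem's shell
  dissolution rate. At equilibrium *S\* = P/k*: a linear within-system curve
  whose slope is entirely an ecosystem property. Because the stock integrates
  production over a trailing window of width ≈ 1/k, slow-dissolving systems
  (hardwater lake, k = 0.05/yr) decouple current impact from current
  population, while fast-dissolving ones (river, k = 2/yr) track it tightly.
- **Instantaneous impact — macrophyte habitat** (`impactcurves.habitat`).
  Population filtration rate (DFR, % of water column/day) drives chlorophyll
  (chl_post = 0.2·chl_pre + 0.8·chl_pre·e^(−0.0347·DFR)), chlorophyll drives
  Secchi depth (log₁₀SD = −0.473·log₁₀chl + 0.803), Secchi depth gives light
  extinction (η = 1.7/SD) and a colonization depth z\* = −ln(0.05)/η, and
  the lake's hypsographic curve converts z\* into colonizable bottom area.
  Basin shape and productivity alone turn the same invader's curve into a
  flat zero (shallow unproductive lake), a smooth saturating rise (deep
  lake), or a sharp threshold (a lake with a littoral shelf).
- **Sampling designs** (`impactcurves.designs`). Within-system,
  cross-system-snapshot, and cross-system-long-term curves built from the
  same landscape of lakes generally disagree; pooled space-for-time
  regressions can even reverse the sign of every within-system response, and
  nonlinear responses open a Jensen gap between snapshot and long-term
  curves.
- **Synthetic populations** (`impactcurves.synthetic`). Seeded lognormal
  AR(1) trajectories calibrated to the order-of-magnitude interannual
  variability of well-studied mussel populations, plus landscape generators.

Intended users: invasion ecologists and quantitative ecologists exploring
how ecosystem context and study design shape density–impact functions.

## Worked example

```python
from impactcurves import (HARDWATER_LAKE, MODERATE_RIVER, TrajectoryParams,
                          equilibrium_stock, generate_trajectory,
                          production_stock_coupling, time_to_fraction)

for params in (HARDWATER_LAKE, MODERATE_RIVER):
    print(params.label, equilibrium_stock(1.0, params),
          round(time_to_fraction(params, 0.95), 1))

series = generate_trajectory(TrajectoryParams(n_years=130, seed=42))
for params in (MODERATE_RIVER, HARDWATER_LAKE):
    r = production_stock_coupling(series, params).correlation
    print(params.label, round(r, 2))
```

prints

```
hardwater lake 20.0 59.9
moderately hardwater river 0.5 1.5
moderately hardwater river 0.99
hardwater lake 0.33
```

At the same production (1 kg/m²·yr) the hardwater lake accumulates 40× more
shell (20 vs 0.5 kg/m²) but needs ~60 years to approach equilibrium where the
river needs ~1.5; and on the same variable population trajectory, annual
impact is a near-perfect predictor of current population size in the river
(r = 0.99) but nearly uninformative in the lake (r = 0.33).

The `examples/` scripts walk each capability end to end
(`shell_accumulation.py`, `macrophyte_habitat.py`, `sampling_designs.py`,
`run_presets_cli.py`), and a thin CLI exposes canonical scenario presets:

```bash
impactcurves shell --preset hardwater-lake --seed 1 --out runs/shell
impactcurves macrophyte --preset shelf-productive --out runs/shelf
impactcurves designs --preset equal-even --out runs/designs
```

Every run writes CSV tables plus a `manifest.json` (resolved options, seed,
package version) sufficient to reproduce it exactly.

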