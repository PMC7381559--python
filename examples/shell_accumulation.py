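"""Cumulative shell accumulation: equilibria, approach times, and decoupling.

Simulates dead-shell standing stock under constant and variable production in
three ecosystems spanning the water-chemistry range where dense mussel beds
occur, then shows how the dissolution rate controls whether the impact seen
in any one year reflects the current population.
"""

import numpy as np

from impactcurves import (
    HARDWATER_LAKE,
    MODERATE_LAKE,
    MODERATE_RIVER,
    TrajectoryParams,
    equilibrium_stock,
    generate_trajectory,
    production_stock_coupling,
    simulate_stock,
    time_to_fraction,
)

print("Equilibrium shell stock at production P = 1 kg/m^2/yr, and time to 95%:")
for params in (HARDWATER_LAKE, MODERATE_LAKE, MODERATE_RIVER):
    s_eq = equilibrium_stock(1.0, params)
    t95 = time_to_fraction(params, 0.95)
    print(f"  {params.label:28s} k={params.k:4.2f}/yr  S* = {s_eq:5.1f} kg/m^2  t95 = {t95:5.1f} yr")
# S* = P/k: the same population leaves 40x more shell in the hardwater lake,
# but the fast-dissolving river equilibrates in ~1.5 yr vs ~60 yr.

series = generate_trajectory(TrajectoryParams(n_years=130, seed=42))
ratio = series.values.max() / series.values.min()
print(f"\nVariable forcing: 130-yr series, interannual max/min ratio = {ratio:.1f}")

for params in (MODERATE_RIVER, HARDWATER_LAKE):
    traj = simulate_stock(series, params)
    res = production_stock_coupling(series, params)
    cv = np.std(traj.stock[1:]) / np.mean(traj.stock[1:])
    print(
        f"  {params.label:28s} stock CV = {cv:.2f}  "
        f"production-stock Pearson r = {res.correlation:+.2f}"
    )
# In the river (k=2) the stock tracks production almost perfectly (r ~ 1);
# in the hardwater lake (k=0.05) the stock integrates decades of history and
# a single year's impact says almost nothing about that year's population.
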