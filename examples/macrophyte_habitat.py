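"""Instantaneous habitat impact: filtration -> clarity -> colonizable area.

Runs the optical chain for six model lakes (three basin shapes x two
productivity levels) and prints the habitat gain at a few population
filtration rates, showing how lake geometry and productivity reshape the
abundance-impact curve of the same invader.
"""

import numpy as np

from impactcurves import Bathymetry, LakeScenario, habitat_chain_table

basins = {
    "shallow (5 m cone)": Bathymetry.conical(5.0),
    "deep (50 m cone)": Bathymetry.conical(50.0),
    "shelf (15 m, shelf 2.5-3 m)": Bathymetry.shelf(),
}
grid = np.arange(0.0, 101.0, 1.0)

for chl_pre, prod in ((3.0, "unproductive"), (30.0, "productive")):
    print(f"\n{prod} lakes (pre-invasion chlorophyll {chl_pre:g} ug/L)")
    print(f"  {'basin':30s} " + "  ".join(f"gain@{d:>3.0f}%" for d in (10, 30, 100)))
    for name, bath in basins.items():
        lake = LakeScenario(bath, chl_pre=chl_pre)
        table = habitat_chain_table(lake, grid)
        gains = [table.loc[table.dfr == d, "gain"].iloc[0] for d in (10, 30, 100)]
        print(f"  {name:30s} " + "  ".join(f"{g:8.3f}" for g in gains))

# Gains are fractions of total lake plan area newly lighted well enough for
# submersed macrophytes (>= 5% surface light) relative to the uninvaded lake.
# The shallow unproductive lake shows 0 at every filtration rate: its bottom
# was fully lighted before invasion. The productive shelf lake is strongly
# nonlinear: most of its gain arrives between 10 and 30 %/day, where the
# colonization depth sweeps across the 2.5-3 m shelf.
shelf = LakeScenario(Bathymetry.shelf(), chl_pre=30.0)
table = habitat_chain_table(shelf, np.arange(0.0, 100.5, 0.5))
marginal = np.gradient(table["gain"].to_numpy(), table["dfr"].to_numpy())
i = int(np.argmax(marginal))
print(
    f"\nshelf-productive: steepest gain at DFR = {table['dfr'].iloc[i]:.1f} %/day "
    f"(colonization depth {table['z_star_m'].iloc[i]:.2f} m, on the shelf)"
)
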