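"""Why the three abundance-impact curve formulations are not interchangeable.

Builds landscapes of lakes whose within-system responses are linear with
different slopes, then fits pooled cross-system curves from snapshot and
long-term-mean sampling and compares them with the within-system truth.
"""

import numpy as np

from impactcurves import (
    EcosystemType,
    Landscape,
    TrajectoryParams,
    compare_designs,
    fit_linear,
    long_term_sample,
    snapshot_sample,
)

three_types = (
    EcosystemType(3.0, "high"),
    EcosystemType(1.0, "moderate"),
    EcosystemType(0.3, "low"),
)

land = Landscape(three_types, (1 / 3, 1 / 3, 1 / 3), n_lakes=30, trajectory=TrajectoryParams())
report = compare_designs(land, seed=1)
print("Mixed landscape, equal type proportions:")
print(f"  within-system slopes: {report.within_slopes}")
print(f"  pooled snapshot slope:  {report.snapshot_fit.slope:.3f} (r^2 = {report.snapshot_fit.r_squared:.2f})")
print(f"  pooled long-term slope: {report.long_term_fit.slope:.3f}")
# The pooled slope is a composition-weighted compromise that matches none of
# the within-system slopes: it would mispredict an abundance change in every
# lake of the landscape.

adversarial = Landscape(
    (EcosystemType(10.0, "strong"), EcosystemType(0.05, "weak")),
    (0.5, 0.5),
    n_lakes=20,
    trajectory=(
        TrajectoryParams(mean_level=1.0, log_sd=0.1),
        TrajectoryParams(mean_level=100.0, log_sd=0.1),
    ),
)
fit = fit_linear(snapshot_sample(adversarial, seed=3))
print("\nAdversarial landscape (strong ecosystems hold sparse invaders):")
print(f"  every within-system slope positive; pooled slope = {fit.slope:+.4f}")
# Space-for-time substitution here predicts that MORE invaders mean LESS
# impact — the wrong sign for every single ecosystem.

convex = Landscape(
    (EcosystemType(1.0, "quadratic", response=lambda a: a**2),),
    (1.0,),
    n_lakes=8,
    trajectory=TrajectoryParams(),
)
curve = long_term_sample(convex, n_years=100, seed=4)
gap = curve.impact - curve.abundance**2
print("\nConvex within-system response (impact = abundance^2), long-term means:")
print(f"  mean Jensen gap (mean impact - impact at mean abundance) = {gap.mean():+.3f}")
# Averaging abundance before applying a convex response understates the
# impact: long-term and snapshot cross-system curves must differ whenever
# within-system responses are nonlinear and abundance varies over time.
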