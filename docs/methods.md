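# Methods

## Shell-hash accumulation model

Standing stock of dead shell S (kg/m²) follows the linear balance
dS/dt = M − kS, with M the mortality flux of shell into the spent-shell pool
(equal to shell production P at steady state) and k (1/yr) the instantaneous
loss rate. Burial and export are assumed negligible, so dissolution is the
only loss; k is an ecosystem property set by water chemistry and movement.
Canonical values span the conditions supporting dense mussel beds: 0.05/yr
(hardwater lake), 0.3/yr (moderately hardwater lake), 2/yr (moderately
hardwater river). Loss rates are sometimes quoted with a negative sign; the
package stores the positive magnitude and applies it as a loss.

Key consequences, all tested: equilibrium stock P/k (linear within-system
curve through the origin, slope 1/k); approach time to a fraction f of
equilibrium −ln(1−f)/k, independent of P (~1.5 yr to 95% at k=2, ~60 yr at
k=0.05); long-run mass balance k·mean(S) = mean(P).

**Integration.** Production forcing is piecewise-constant on an annual grid,
so each interval is advanced with the exact closed-form exponential update
rather than Euler stepping — there is no truncation error and results are
independent of reporting resolution. Trajectories report stock at year
marks; the final interval is closed one median grid-spacing past the last
mark so every production value has an end-of-interval stock.

**Coupling diagnostic.** The production–stock relationship pairs each year's
production with that year's end-of-year stock and reports a Pearson r. The
first max(5/k, 10) years are discarded so the initial-condition transient
cannot contaminate the scatter (the transient decays as e^(−kt); 5/k years
leaves < 1%). Constant-production series are flagged as having an undefined
correlation rather than raising.

## Macrophyte-habitat model

Four stages map population filtration rate (DFR, % of the water column
filtered per day) to the gain in colonizable bottom area:

1. chl_post = 0.2·chl_pre + 0.8·chl_pre·e^(−0.0347·DFR). The 0.2 refractory
   fraction is phytoplankton biomass beyond the reach of filtration (the
   floor of the response); 0.0347 is per (%/day).
2. log₁₀(Secchi depth, m) = −0.473·log₁₀(chl, µg/L) + 0.803 — the classical
   chlorophyll–clarity regression from the eutrophication literature.
3. η = 1.7/Secchi (per m); colonization depth z* = −ln(0.05)/η, the depth
   receiving 5% of surface light, taken as the macrophyte survival limit.
   The constant 1.7 is the standard Secchi–extinction product; the division
   runs this way (not Secchi/1.7) because η must fall as clarity rises —
   the physically sensible form, and the one under which the shallow
   unproductive lake (baseline z* ≈ 6.66 m > 5 m bottom) shows the expected
   zero response at every filtration rate.
4. The hypsographic curve (cumulative plan-area fraction vs depth) converts
   z* to colonizable area. Impact is reported as the gain in that fraction
   over the DFR = 0 baseline — a dimensionless fraction of total lake plan
   area, so lakes of different absolute size are comparable; multiply by a
   surface area for m².

Model basins: conical 5 m ("shallow") and 50 m ("deep"), with the closed
form fraction(z) = 1 − (1 − z/z_max)², which depends only on z/z_max; and a
15-m "shelf" lake concentrating a configurable fraction (default 0.5) of its
plan area between 2.5 and 3 m depth, the remaining area split between the
shallower and deeper spans in proportion to their depth extents and
interpolated linearly. The 0.5 shelf fraction is a design choice — "a
pronounced shelf" pinned to a concrete number — and is exposed in the
config; the tested claim about the shelf lake is a containment property
(the steepest marginal gain occurs where z* lies within 2.5–3 m, at DFR
within 10–30 %/day), not an exact curve. Tabulated bathymetries are
accepted for real hypsographic data.

Productivity scenarios: pre-invasion chlorophyll 3 µg/L (unproductive) and
30 µg/L (productive). Default DFR grid 0–100 %/day in steps of 1.

The chain is instantaneous: the light climate is assumed to follow
filtration with no lag, and macrophyte population dynamics (which do lag)
are out of scope, as are nutrient feedbacks and seasonal stratification.

## Sampling-design comparison

Within-system responses are linear through the origin by default (zero
invader, zero impact), with slope an ecosystem-type property; nonlinear
responses can be supplied as callables. Landscapes hold ecosystem types in
stated proportions; lakes are assigned to types by exact largest-remainder
rounding (ties to the earlier type).

- **Snapshot sampling** visits each lake once at a uniformly random year of
  its abundance trajectory — one (abundance, impact) point per lake. The
  uniform-year rule is a design choice; any single-visit scheme shares its
  qualitative artifacts. A deterministic variant (`even_snapshot`) places
  each type's lakes on an even abundance grid, the idealized survey.
- **Long-term sampling** reports per-lake means of abundance and of impact,
  averaging impact year-by-year through the response so that nonlinear
  responses exhibit the Jensen gap (mean of the response vs response of the
  mean).
- **Fitting** is unconstrained ordinary least squares through all pooled
  points — deliberately including an intercept even though generation is
  origin-through, because that is how a field analyst would fit.

`compare_designs` reports the per-type within slopes, both pooled fits, a
sign-agreement flag, and the mean absolute error of the pooled line against
each type's own response over the observed abundance range (how badly the
cross-system curve would mispredict a within-system abundance change).

Exact identities used as tests: with a single linear type all three slopes
coincide to machine precision; with equal type counts on a common abundance
grid the pooled OLS slope equals the mean of the type slopes (hence lies
within [min, max]); an adversarial landscape (high-slope types at low
abundance, low-slope types at high abundance) yields a pooled slope opposite
in sign to every within-system slope.

For cumulative impacts, the temporal weighting window that links abundance
history to current impact is realized implicitly by the exponential kernel
e^(−kτ) of the shell model (compose `designs` sampling with `shell_hash`
trajectories); no separate window estimator is provided.

## Synthetic trajectories

Abundance/production trajectories are stationary lognormal AR(1) series:
log values follow x_t = µ + ρ(x_{t−1} − µ) + ε_t with ε_t ~ N(0, σ√(1−ρ²)),
started in the stationary distribution (no transient). `mean_level` is the
median (e^µ); σ (`log_sd`) is the stationary log-scale SD; ρ (`autocorr`)
the lag-1 autocorrelation. The form is chosen because biomass is positive
and its interannual variation is naturally multiplicative.

The default preset (25 yr, σ = 0.6, ρ = 0.3) is calibrated so the median
max/min ratio within a series is ≈10 (Monte Carlo over 4000 seeds gives
9.9), matching the order-of-magnitude interannual variation of well-studied
riverine mussel populations. σ = 0.8 would give a median ratio of ≈21 —
about twice the target — which is why 0.6 is the default. ρ and the series
length are not identifiable from the order-of-magnitude statement alone;
0.3 encodes mild persistence and 25 yr a typical long monitoring record.
Per-lake seeds derive deterministically from (master seed, lake index) via
`numpy.random.SeedSequence`, so landscapes are reproducible and extensible
lake by lake.

What the generator does *not* emulate: demographic mechanisms, boom-bust
cycles, observation error, trends, or spatial correlation among lakes
(trajectories are independent). Passing tests therefore show the models'
internal logic under idealized forcing, not agreement with any field
dataset.

## Numerical choices and degenerate inputs

- Exponential updates are exact per interval; the only tolerance-bearing
  comparisons are against independent integrators in tests (< 0.1%
  relative over a century).
- `time_to_fraction` uses log1p for accuracy at small fractions.
- Pearson correlation on constant production is flagged undefined, not an
  error; fits on degenerate abscissae raise.
- Per-capita effects interpolate the curve linearly; the marginal effect is
  a centered finite difference with step 10⁻⁴ of the observed abundance
  range (one-sided at the ends); the average effect is undefined (NaN,
  flagged) at zero abundance.
- Colonization depths beyond the maximum depth saturate the area fraction
  at 1; a survival light fraction of 1 gives z* = 0.

## Problem sizes

Test and script workloads are desk-scale by design: 130-yr series for the
coupling contrast (the slow system's burn-in is 100 yr), 2000-yr series for
mass balance, 10⁴-yr series for stationarity checks, ≥1000 seeds for the
range calibration, and landscapes of 10–60 lakes. All run in seconds on one
CPU.

## Known limitations

- The shell model omits burial, export, transport, and any mapping from
  mussel density/biomass to shell production; abundance *is* the production
  rate.
- The chlorophyll response is a single empirical curve; real filtration
  impacts depend on mixing depth, stratification, and refuge effects.
- The shelf-lake area distribution is a synthetic archetype; real
  hypsographic curves should be supplied as tabulated bathymetries.
- Cross-system artifacts are demonstrated constructively on synthetic
  landscapes; magnitudes in real surveys depend on the actual heterogeneity
  of within-system responses.
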