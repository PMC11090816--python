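# Methods

This note documents the models implemented in `phytoclim`, the choices made
where the published protocol leaves the formulation open, and what the
synthetic-data validation does and does not establish.

## Growth kernel (`phytoclim.ttr`)

State per plant: shoot and root structural mass `Ms, Mr` and substrate
pools `Cs, Cr, Ns, Nr` (arbitrary mass units, all non-negative). The
monthly explicit update is, with concentrations `cs = Cs/Ms` etc.:

```
U_C = a_max(T, I, CO2) * trap(W; c_moist) * f_N(ns) * Ms / (1 + Ms/K_shade)
U_N = sigma_N * trap(T; n_temp) * trap(W; n_moist) * Mr / (1 + Mr/K_root)
T_C = g_C * (cs - cr) * Mh,   T_N = g_N * (nr - ns) * Mh,   Mh = Ms*Mr/(Ms+Mr)
G_s = k_g * trap(T; g_temp) * cs * ns * Ms     (capped by substrate budget)
G_r = k_g * trap(T; g_temp) * cr * nr * Mr     (capped by substrate budget)
Ms' = Ms + G_s - lambda*Ms                      (litter)
Cs' = Cs + U_C - f_C*G_s - T_C - mu*Cs          (and analogously for Cr, Ns, Nr)
```

`trap(x; p1..p4)` is the trapezoidal response (0 outside `(p1,p4)`, 1 on
`[p2,p3]`, linear limbs); `f_N(ns) = floor + (1-floor)*ns/(ns+h)` is the
saturating shoot-nitrogen dependence of carbon uptake. The 18
species-specific parameters are the four trapezoids (temperature and
moisture for N uptake, moisture for C uptake, temperature for growth) plus
`(h, floor)`. Soil nitrogen is uniform across cells, so N uptake depends on
climate only. Monthly mean temperature drives all responses; min/max
temperatures enter only the evapotranspiration model.

Three closures are this implementation's own (the transport-resistance
literature admits several):

* **Self-shading saturation** `M/(1 + M/K)` on both uptakes. Without it the
  update is linear in mass and grows without bound; with it every cell has
  a finite equilibrium biomass, which is the quantity the rest of the
  pipeline consumes.
* **Substrate budget caps.** Growth and transport in one month may consume
  at most the substrate present after turnover. This makes the explicit
  step exactly mass-conserving (the non-negativity clamp never triggers),
  which the test suite asserts step by step.
* **Uptake ceiling.** `a_max = min(alpha*I, Vmax * exp(-((T-Topt)/s)^2/2) *
  g(CO2))` with `g = (CO2-Gamma)/(CO2+K)` for C3 (compensation point 40
  ppm, K = 300 ppm) and `g = CO2/(CO2+60)` for C4. This reproduces the
  qualitative contracts (zero light -> zero uptake; C3 monotone in CO2; C4
  nearly CO2-saturated above ~400 ppm; interior thermal optimum) with a
  form simple enough to verify against direct evaluation.

Universal constants (one table, `TTRConstants`): `sigma_N = 0.05`,
`f_C = 0.45`, `f_N = 0.02`, `k_g = 20`, `g_C = g_N = 0.5`,
litter `lambda = 0.1`/month, substrate turnover `mu = 0.1`/month,
`K_shade = K_root = 5`, initial state (0.05, 0.05, 0.005, 0.005, 0.001,
0.001), biomass floor 0.05 (below it a cell counts as unsuitable). The
rates were chosen so that (a) under constant favourable forcing the map
converges to a genuine fixed point rather than a period-2 cycle (strong
transport/growth rates destabilize the explicit monthly step), and (b) the
slowest relaxation time is ~10 months, so equilibrium is reached within a
few tens of annual cycles. The fixed point is cross-checked against an
independent nonlinear root solve of the one-month map.

Equilibrium iteration: each (species, cell) pair runs 12-month cycles from
the standard initial state until the annual-mean biomass changes by less
than `1e-4` (relative; `2e-3` with a 15-cycle cap inside the optimizer
loop, where only the likelihood ranking matters) or 80 cycles elapse. Cells
on very slow near-marginal growth trajectories can satisfy the per-cycle
tolerance before their true plateau; this affects a few percent of cells at
worst and is documented in the corresponding test. The inner loop is a
compiled (numba) scalar kernel, verified against step-by-step single-plant
updates.

## Soil moisture (`phytoclim.soil`)

Hargreaves-type PET (`0.0023 * 0.408 * Ra * (T+17.8) * sqrt(Tmax-Tmin)`,
clamped at 0, times days in month) drives a single-bucket model bounded by
wilting point and field capacity; actual evapotranspiration is
`min(PET * (W-wp)/(fc-wp), available water)` and excess above `fc` is lost
as runoff/drainage. The 12-month cycle is iterated to a periodic steady
state (tolerance 0.01 mm, max 50 cycles); the steady state is independent
of initialization and closes the annual water balance to < 0.01 mm, both
asserted by tests. No snow store, soil layering or vegetation feedback.

## Synthetic worlds (`phytoclim.synthetic`)

The generator emulates the *statistical structure* the analysis assumes:
quadratic poleward cooling with poleward-growing, hemisphere-antiphased
seasonality; smooth (Gaussian-filtered) spatially autocorrelated
precipitation, soils and land mask; radiation as a deterministic function
of latitude band and month; ambient CO2 338 ppm. Scenarios apply a uniform
temperature shift plus seeded spatially smooth pseudo-GCM noise (default sd
0.5 degC), a precipitation scale factor, and a CO2 replacement (438/677 ppm
defaults for the reduced/high pathways); radiation and soils are held
fixed and future soil moisture is re-derived from the bucket model.

Virtual species draw their trapezoids around the annual-mean climate of a
random anchor cell, which keeps true suitable areas non-empty; draws with
prevalence below 3% are rejected and redrawn. Occurrences are sampled
uniformly (optionally with a well-sampled-disc bias) from truly suitable
cells only, one record per cell — so a perfect refit has TSS 1 against
truth, the premise of the recovery tests.

What the generator does **not** emulate: real climate physics (no
orography, circulation, interannual variability), observational coordinate
error, taxonomic misassignment, or the strong clumped sampling biases of
herbarium data beyond the simple disc-bias option. Passing tests therefore
demonstrate the statistical machinery is correct and recoverable under the
assumed data structure, not that real-data fits are unbiased.

## Species fitting (`phytoclim.fitting`)

Environmental zones: k-medoids (k = 20) on repeated subsamples of
standardized monthly forcing features projected to 10 principal
components, keeping the lowest-cost medoid set, followed by a single
discriminant-analysis reassignment pass. Presences above the 400 cap are
subsampled by largest-remainder apportionment over zone proportions;
pseudo-absence zone weights are proportional to inverse presence-zone
proportions (zones without presences are assigned the minimum observed
proportion before inverting, since the inverse rule is undefined at zero),
with per-zone counts drawn multinomially and cells uniform within zones.
Species with fewer presences than zones get exactly 20 pseudo-absences;
at least 7 presences are required.

The optimizer is scipy's differential evolution (rand1bin, F = 0.8,
CR = 0.9, Sobol initialization, deferred updating, no polish) over a gap
encoding — each trapezoid is searched as `(p1, gap12, gap23, gap34)` with
non-negative gaps so breakpoint ordering holds by construction — with
bounds derived from the climate envelope of the sample. Each candidate's
two cloglog calibration coefficients are profiled out by a Fisher-scoring
fit batched across the population (two parameters, closed-form normal
equations, small ridge for degenerate candidates); the single-fit path is
verified against statsmodels GLM. `ln(B + 1e-6)` is the linear predictor;
the binarization cutoff scans observed scores, their midpoints and a
sentinel above the maximum, taking the lowest maximizer of TP + TN.

Default DE budget mirrors the protocol (1000 generations, population
10 x 18); validation runs use 200 generations with population 2 x 18, the
largest budget at which the 20-species recovery experiment completes in
minutes on one CPU — at that budget all probed species recover truth-TSS
well above the 0.7 acceptance bar.

## Phytoclimates and zones (`phytoclim.phyto`)

Growth-form surfaces are plain fractions of accepted species' binary maps
per form (forms with zero modelled species are an error at the operation
level; the pipeline backfills an empty form with its best-TSS fits and
logs a warning, so tiny demonstration runs remain well-defined). The zone
model is EM for a Gaussian mixture constrained to a shared covariance
eigenvalue profile with free volume and orientation per component
(Celeux–Govaert M-step with a few inner iterations), seeded k-means
initialization, `1e-6` diagonal regularization, log-likelihood tolerance
`1e-6` per observation. The implementation reproduces the R package
mclust's "VEV" log-likelihood on a frozen fixture to < 0.01 and its free
parameter count exactly; BIC is reported in the statistics convention
(`-2 logL + p log n`, smaller better). The significance threshold is the
5th percentile (linear interpolation) of the `k(k-1)/2` pairwise centroid
distances; k defaults to 18.

## Risk indices (`phytoclim.risk`)

The three indices are Euclidean distances in the 14-dim suitability space;
pools for novelty/disappearance are all land cells globally, including the
focal cell's own counterpart, so both are bounded by local change.
Nearest-analogue search uses a k-d tree with an explicit lowest-index
tie-break and recomputes final distances elementwise, making the
accelerated path bit-identical to the O(N^2) scan (asserted exactly on
500-cell surfaces). One shared threshold is used for significant change,
novelty and disappearance (configurable). Ensembles are summarized two
ways, matching the two uses downstream: per-growth-form median
suitabilities feed zone assignment; per-index cellwise medians feed the
risk maps.

## Pipeline scales used in validation

The validation suite runs: parameter recovery on a 30x30 world (810 land
cells, 20 species, 200 presences each, DE 200 generations x population
36); end-to-end null and directional runs on 20x20 worlds with 28 species
and a 30-generation DE budget (the null run's exact zeros are independent
of fit quality; the directional run tests index consistency, not fit
accuracy); subsample stability with 300 species per growth form (4200
total, using their true maps); and a
5-component mixture recovery in 14 dimensions. These sizes were chosen so
the full validation completes in minutes on a single CPU while keeping
every stage's statistical behaviour observable.

## Known limitations

* The growth model's equations beyond the documented contracts are this
  package's closure; absolute biomass values are in arbitrary units and
  only the induced suitability geometry is meaningful.
* Sample-TSS can understate true-map accuracy because pseudo-absences may
  fall in truly suitable cells; the acceptance filter inherits this
  conservatism from the field protocol.
* Tiny grids make the Gaussian mixture's covariance estimates noisy;
  `k_zones` should stay well below `n_land / 10`.
* No reprojection: all grids are abstract equal-area grids; real-raster
  ingestion expects data already on such a grid.
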