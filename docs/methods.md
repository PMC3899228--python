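# Methods

This note documents the models and procedures implemented in
`shorewatch`, the assumptions behind them, the defaults and why they
were chosen, and what the synthetic validation does and does not
demonstrate.

## Geolocation

**Earth model.** Distance by reticle drop is computed on a sphere of
effective radius `R_eff = R / (1 − k)`, with `R = 6 371 000 m` and
refraction coefficient `k = 0.13`, the standard marine-survey treatment
of atmospheric refraction. Zero reticles is the visible horizon; each
reticle adds a fixed angular depression. The reticle spacing
(`0.00497 rad` per reticle) is the conventional value for 7×50 marine
binoculars; it is an *assumption*, configurable in `GeodeticConfig`,
because surveys rarely calibrate it. The geometry is the exact
ray–sphere intersection, not the small-angle approximation; tests
validate it against an independent numerical ray-trace to 0.5%.

**Observer height.** Platform heights are surveyed above low water;
the instantaneous observer height subtracts the tidal height above
extreme low tide at scan time. A rising tide therefore shrinks every
estimated distance for a fixed reticle reading.

**Projection.** Positions live in a local ellipsoidal transverse
Mercator frame on WGS84 (central meridian −4.785°, latitude of origin
52.75543°, scale 1.0), implemented with the classical series and a
Newton-inverted meridian arc; forward/inverse round-trips are exact to
well below 0.01 m across the ±20 km domain. Bearing → displacement uses
plane trigonometry in that frame: grid convergence is < 0.2° over the
domain, far below the ~0.5° bearing-rounding error.

## Detection-distance analysis

The inflection point of an accumulation curve is estimated as the
breakpoint of a continuous two-segment least-squares fit, grid-searched
over breakpoints at observed-distance quantiles (50 candidates between
the 5th and 95th percentiles), with the second slope constrained not to
exceed the first. A curve whose two-segment fit improves the single-line
SSE by less than 1% is flagged "no decline" and returns the maximum
distance.

Two fitting scales are offered. `scale="distance"` fits on the raw
distance axis, appropriate when the observed curve rises linearly below
the inflection (as published shore-survey curves typically do).
`scale="area"` fits against squared distance: if animals are spread
uniformly over the viewshed, cumulative count grows with surveyed
*area* while detection is certain, so the bend in the area scale marks
the inflection radius. Under the synthetic generator (uniform use, a
linear-in-distance decline to zero at twice the inflection radius) the
declining branch is curved on either scale, so the two-segment chord
settles somewhat beyond the true kink; the closed-loop test asserts the
estimate lands in [0.9 r₀, 1.5 r₀] rather than on r₀. On exactly
piecewise-linear curves the breakpoint is recovered within one
candidate step.

Curve pooling replaces visual judgement with a reproducible rule: two
curves pool when their two-sample Kolmogorov–Smirnov statistic is at
most 0.1 (single-linkage over pairs), with a config override to force
any grouping.

Filtering retains sightings whose sea state is within the species cap
(default Beaufort ≤ 2 for both species; rougher states for a species
are handled through their shorter inflection radii) and whose distance
is within the (site, species, sea-state) radius; identical positions
within one 10-minute scan are treated as re-sightings and dropped.

## Covariates

* **Slope/aspect** use Horn's 3×3 stencil (the common GIS default);
  aspect is the downslope azimuth, i.e. the direction of increasing
  depth, clockwise from north; flat cells carry NaN.
* **Neighbourhood SD** is taken over a cell plus its *k = 5* nearest
  neighbours in the fixed order N, E, S, W, NE (rook before diagonal) —
  honouring the unusual 5-cell neighbourhood of the original workflow
  literally; `k` is configurable up to the full Moore neighbourhood.
  Sample SD (ddof = 1) is used. Cells with incomplete stencils are
  nodata.
* **Currents** follow the oceanographic *toward* convention. Snapshot
  grids (300 m, one per half-hour tidal state from HW−6 to HW+6) are
  interpolated linearly in time on the (u, v) components and resampled
  bilinearly on components, not speed, to avoid speed-up bias at
  direction shear.
* **Stratification** is log10(h/U³) with U floored at 0.01 m/s so slack
  water does not produce infinities; the mean-stratification surface
  uses the tidal-cycle mean speed per cell. Regime bins: < 2.3 mixed,
  2.3–2.75 switching, 2.75 frontal boundary, 2.75–3.5 stratified,
  > 3.5 strongly stratified.
* **Temporal covariates**: tidal state is the signed time to the
  nearest high water (period 12.42 h, range ±6.21 h); lunar cycle is
  the signed time in days to the nearest neap (period 14.77 d, range
  ±7.39 d), with neap instants found as parabola-refined minima of the
  high-water-height envelope. One neap per half spring–neap cycle is
  used — the two monthly neaps are deliberately not distinguished.
  Both covariates are treated as circular downstream.

## Kernel core areas

Effort is balanced by subsampling an equal number of
simultaneous-coverage scans per sector (seeded, reproducible);
sightings in sector-overlap zones get weight 0.5 against double effort.
The density estimator is a fixed bivariate Gaussian mixture with a full
2×2 bandwidth matrix chosen by smoothed cross-validation: the classic
two-term criterion with a normal-scale pilot, minimised over SPD
matrices through a log-Cholesky parameterisation (Nelder–Mead from the
normal-reference start, deterministic). Point sets smaller than 10 fall
back to the normal-reference plug-in, flagged in the metadata. Weights
generalise the criterion through the effective sample size
(Σw)²/Σw².

Percent-volume contours rank cells by density and take the smallest set
reaching p% of the on-grid volume; areas are cell-mask areas (raster
percent-volume semantics), not smoothed polygon areas, and land is not
excluded by default, both matching the conventional GIS workflow.
Surfaces integrate to 1 ± 1% whenever the grid holds the kernel mass;
the 50% contour of an isotropic Gaussian reproduces the analytic area
2πσ²ln 2 within the grid discretisation.

## The IPP habitat model

Sightings are a realisation of an inhomogeneous Poisson point process
over the realised effort (each scan's sector wedge up to its inflection
radius, at scan times). The IPP likelihood is approximated by
infinitely weighted logistic regression: response 1 / weight 1 for
sightings, response 0 / weight W for availability points, default
W = 1000 with a convergence check (slopes move by < 10⁻³ when W is
raised to 4000).

**Availability sampling.** Two points per scan (configurable), uniform
by area over the wedge (r = R√u, θ uniform). Two corrections keep the
availability sample a faithful quadrature of the effort measure:

1. *Area weights.* The wedge area varies with the sea-state-specific
   radius while the count per scan is fixed, so each availability point
   carries a case weight proportional to its scan's wedge area (scaled
   to average W). Without this, small-wedge scans are over-represented
   per unit area and covariates correlated with sea state are biased.
2. *Reticle-ring alignment.* Distances are measured on discrete
   half-reticle rings, so a distance filter actually admits every
   position whose *nearest ring* is inside the radius; the effective
   boundary sits midway between the innermost admitted and first
   excluded ring, and it moves with the tide through observer height.
   The availability radius per scan is set to that quantized boundary.
   Without this, the admitted area oscillates coherently with tidal
   phase and the tidal-state effect is attenuated by several percent —
   a measurement-process bias worth knowing about in real reticle
   surveys.

**Smooth terms.** 1-D smooths are penalized natural cubic regression
splines with knots at covariate quantiles (k = 10) — the same function
space and second-derivative penalty as 1-D thin-plate smoothing, in a
closed-form, numerically stable parameterisation. Cyclic covariates
(tidal state 12.42 h, lunar cycle 14.77 d, aspect and current direction
360°) use cyclic cubic regression splines (k = 8) whose value and first
two derivatives match at the period ends. The spatial surface is a
tensor product of two marginal cubic bases (5×5) with the summed
marginal penalty S₁⊗I + I⊗S₂ under a single smoothing parameter — one λ
instead of two trades a little anisotropic flexibility for a much
smaller smoothing search. Site and sea state are unpenalized factors,
reference level first by sorted label. Penalized columns are centred on
the training data so the intercept stays identifiable.

**Smoothing selection** uses a GCV-type score n·D/(n − edf)² over a
log-spaced λ grid (10⁻²…10⁶), coordinate descent over terms, two
sweeps. **Model selection** is forward, scored by leave-one-day-out
cross-validated log-likelihood: weighted Bernoulli log-likelihood on
the held-out day, smoothing parameters frozen at their full-data
selection (refitting λ per fold is configurable but costly). Selection
stops at the first non-positive best ΔCVLL; remaining candidates are
reported with their rejected deltas. Collinear covariates (|r| ≥ 0.8)
are screened beforehand, the loser chosen by a biological priority list
(stratification measures outrank raw current speed and distance
proxies).

Deviance explained is 100·(1 − D/D₀) against the weighted null
deviance; the null model scores exactly 0. Effects are reported as rate
ratios exp(β) and as profile curves with other covariates held at
training medians (factors at reference).

## Synthetic studies

The generator emulates the study system: an island (nodata mask) in a
10 × 8 km domain, depth shoaling from ~45 m (west) to ~14 m (east) with
a locally deeper gully east of the island; semidiurnal tides
(12.42 h) with a 14.77-day spring–neap envelope (HW heights 2–4 m);
rectilinear currents flowing NW on the flood, slack at HW−4, peaking
near HW, capped at 3 m/s, with a flood-phase wake eddy west of the
island; four platforms (17/17/38/60 m) with ~110° sectors; 10-minute
scans with a shared persistent Markov sea-state chain on Beaufort 0–4
(symmetric walk, uniform stationary law).

Sightings are drawn from the IPP with log-intensity
β₀ + β_depth·(depth − 25)/10 + β_tide·cos(2π·tidalstate/12.42)
(defaults +0.5 and +0.6 for porpoises; −0.4 and +0.3 for Risso's),
thinned by a detection function equal to 1 inside the sea-state-specific
inflection radius and declining linearly to zero at twice that radius,
and recorded as measurements quantized to 0.5 reticles and 1° of
bearing — reproducing the ring artefacts of real reticle data. The
default schedule (30 days × 50 scans/day × 4 platforms = 6 000 scans)
is sized so that roughly 2 000–4 000 porpoise sightings survive
filtering, enough for the ±15% coefficient-recovery property to have
statistical headroom; smaller studies are a constructor argument away.

**What the synthetic validation shows** — that the full chain
(measurement quantization → geolocation → filtering → availability
quadrature → IWLR) recovers the generating coefficients without
systematic bias, and that each derived surface and statistic matches
closed forms or independent oracles. **What it does not show** — the
generator has no animal movement or group structure (points are
independent given the intensity), no responsive behaviour, no
observer-skill heterogeneity, hydrodynamically naive currents, and a
detection decline of known parametric shape; agreement here does not
certify any of those aspects of real surveys.

## Numerical choices and degenerate inputs

* Logistic fits run penalized IRLS with a 10⁻⁸ ridge for conditioning;
  separation (standardized |β| > 20) triggers a warning and a 10⁻³
  ridge refit.
* Probabilities are clipped to [10⁻¹², 1 − 10⁻¹²] in likelihoods;
  linear predictors to ±35.
* Inflection estimation requires ≥ 20 points; all-nodata rasters,
  empty distance lists, zero-variance point sets and single-class
  responses raise typed errors rather than returning NaNs.
* CV folds that would leave a single response class, or hold out no
  availability points, are skipped with a warning.
* Ties in quantile knots fall back to an even knot spread; availability
  redraws on nodata are capped at 100 rounds.

## Known limitations

* The IWLR approximation inherits the usual availability-sample Monte
  Carlo error; coefficient standard errors are not reported (the CV
  selection is the inferential instrument, as in the original
  workflow).
* The broken-stick inflection estimator is biased outward when the
  detection decline is smooth; treat estimated radii as conservative
  upper regions, not sharp boundaries.
* Percent-volume areas depend on the analysis grid resolution at the
  few-percent level.
* `surface_correlation` is a plain Pearson correlation across cells;
  spatial autocorrelation makes its nominal significance meaningless,
  so none is reported.
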