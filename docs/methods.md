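# Methods

## The movement model

A *connection* is one tagged bird detected at one feeder and
subsequently at a different feeder of the same network, within the same
season and within a duration cutoff. Connections are derived from raw
RFID reads in two steps.

**Visit bouts.** Raw reads are collapsed into maximal runs of one tag at
one feeder with inter-read gaps no longer than `bout_gap` (default
5 min). Antenna re-reads seconds apart are one visit; a bird that leaves
and returns after the gap threshold has made two. The bout is the unit
between which movements are defined: without it, "visiting first one and
then a different feeder" is ambiguous for streams with dozens of
same-perch reads per minute.

**Connection events.** For each tag, every ordered pair of *consecutive*
bouts at distinct feeders is a candidate event (`depart` = end of the
first bout, `arrive` = start of the second). A chain F1→F2→F3 yields
F1→F2 and F2→F3, never F1→F3, and a revisit A…A…B yields only A→B.
Candidates are discarded, with per-reason counts, when they

- take longer than `max_duration` (default 48 h — most connections in
  feeder studies happen within two days, and slower transits likely
  follow indirect routes that say nothing about the corridor between
  the two feeders);
- cross networks; or
- straddle a season boundary (the models require a single-season
  assignment; an event's season is that of its arrival).

Whether "two days" means 48 h or two calendar days is a genuine
ambiguity; we use 48 h and expose it as configuration. The year is split
into four equal seasons (autumn 1 Sep–30 Nov, winter 1 Dec–28 Feb,
spring 1 Mar–31 May, summer 1 Jun–31 Aug) that partition the study
window exactly; every in-window instant has one season.

Timestamps are stored as UTC; naive input is interpreted in a
configurable local study timezone. Exact duplicate `(tag, feeder,
second)` triples are dropped and counted — field loggers emit them
within one polling cycle.

## Landscape covariates

The habitat a bird likely uses when moving between a feeder pair is an
ellipse centred on the pair midpoint with its major axis along the
inter-feeder segment: semi-major `0.75 d`, semi-minor `0.25 d`
(`d` = pair distance), i.e. a buffer of `0.25 d` beyond each feeder and
a fixed 3:1 length:width ratio. Within the buffer:

- **Vegetation cover** — the percentage of raster pixels whose *centre*
  falls inside the ellipse and that hold tall vegetation: canopy height
  above 0.7 m **and** a vegetation index above a threshold (default 0.2
  on an NDVI-like scale; the index test can be disabled). Pixel-centre
  membership rather than area weighting is simple, deterministic, and
  adequate at the 2 m pixel scale relative to buffers spanning tens of
  metres.
- **Road gaps** — the number of distinct road polylines whose
  intersection with the ellipse has positive length (a tangency touching
  only the boundary does not dissect the buffer; a road crossing twice
  counts once, since feature identity defines "a road"). Three or more
  gaps are pooled with two, giving an ordered factor 0/1/2+.
- **Distances** — Euclidean pair distance, and the minimum distance from
  either feeder to any of the network's ringing (bird-catching) sites.
  Coordinates are planar metres in any projected CRS; at network extents
  of ~0.5 km² no geodesy is warranted.

Rasters are single-band regular grids handled by a small container with
ESRI ASCII grid text I/O; roads are GeoJSON LineString features.

## The hurdle mixed models

Presence and frequency are modelled separately; the hurdle factorizes,
so the two parts are fitted independently and their log-likelihoods add.

**Zero part (structural connectivity).** A binomial (logit) GLMM on the
complete species × pair × season grid, absences included. Fixed effects:
vegetation cover, pair distance and ringing-site distance (each z-scored
over the fitted rows, n−1 denominator), road-gap class (baseline 0),
season (baseline summer) and species (baseline blue tit).

**Count part (functional connectivity).** A zero-truncated Poisson
(log link) GLMM on per-bird pair-season counts where ≥ 1; per-row
log-likelihood `y·η − λ − log(1 − e^{−λ}) − log y!` with `λ = exp(η)`,
conditional mean `λ/(1 − e^{−λ})` and observed information
`m(1 + λ − m)`. Truncation reflects the sampling design: a row exists
only because a connection happened, so zeros are structurally absent. A
plain-Poisson comparison fit is available through the estimators'
shared interface.

**Random effects.** Each row (a feeder pair) belongs to *both* of its
feeders: one feeder-level variance component whose random-effect design
has two unit entries per row, so the row-level random part is
`u_a + u_b` with a single shared variance. Treating the two positions
as one grouping keeps the variance identifiable while capturing that a
pair is replicated across seasons and shares its feeders with other
pairs. The count part adds an ordinary tag-identity intercept for
birds that connect repeatedly.

### Estimation

The marginal likelihood is approximated by Laplace; multi-membership
makes the random effects non-nested, which rules out one-dimensional
adaptive quadrature. Fitting proceeds in two stages:

1. *Profiled stage.* At fixed variance parameters θ = log σ, a joint
   penalized Newton iteration maximizes
   `ℓ(y|β,u) − ½ uᵀD⁻¹u` over (β, u) (step-halved, warm-started),
   and `ℓ_p(θ) = ℓ(y|β̂,û) − ½ ûᵀD⁻¹û − ½ log|I + D ZᵀWZ|` is
   maximized over the one or two θ dimensions by Nelder–Mead. This is
   fast and gives excellent starting values, but for binary responses it
   attenuates coefficients noticeably (the curvature term's β-dependence
   is ignored) — roughly 10% on intercepts at the study's data scale in
   our simulations.
2. *Full Laplace refinement.* L-BFGS-B over (β, θ) jointly on the full
   Laplace objective with an inner penalized solve for u only. The
   β-gradient is analytic: the envelope theorem removes the
   u*-dependence of the penalized part (leaving `Xᵀ(y − μ)`), and the
   curvature term differentiates through the trace identity
   `∂ log|H_u|/∂β = Σᵢ cᵢ w′ᵢ ∂ηᵢ/∂β` with `cᵢ = [Z H_u⁻¹ Zᵀ]ᵢᵢ` and
   `∂η/∂β = X − Z H_u⁻¹ ZᵀWX`. The θ directions use forward
   differences. The gradient is verified against numeric
   differentiation in the test suite. In recovery simulations the
   refinement removes the binary-response attenuation (biases of a few
   percent remain, consistent with ordinary finite-sample ML bias).

Inner Newton convergence is gradient ∞-norm < 1e-8; starting values are
the GLM fit (β) and log σ = −1. Wald SEs come from the β-block of the
inverse joint penalized Hessian at the optimum (conditional on θ̂, the
convention of mixed-model software); 95% CIs are `β̂ ± 1.96·SE`, and CIs
are Wald rather than profile. With a variance pinned at zero the u block
vanishes and the fit reduces exactly to the GLM, which is cross-checked
against independent GLM implementations. Degenerate inputs error
informatively: single-valued binary responses, counts below 1, rank
deficiency, diverging coefficients (|β| > 30, the separation
diagnostic), and inner non-convergence (reported with the gradient
norm).

### R² and significance

Marginal and conditional R² follow the variance-partition
(Nakagawa–Schielzeth) definitions: `R²m = σ²_f / (σ²_f + σ²_r + σ²_d)`
and `R²c` adds `σ²_r` to the numerator, where `σ²_f` is the variance of
the fixed linear predictor over the fitted rows and `σ²_r` counts each
factor's variance times its membership multiplicity (the feeder term
contributes `2σ²`). The distribution-specific variance `σ²_d` is π²/3
for the logit model and `ln(1 + 1/λ̄)` for the log-link count model,
with `λ̄ = exp(mean η_fixed + σ²_r/2)` — an *untruncated* lognormal
approximation, a stated limitation for the truncated family. No
multiple-testing correction is applied; stars follow the conventional
0.05/0.01/0.001 tiers.

### Pooled cross-network models

For the cross-network comparison, connections are pooled over seasons
and species to one row per feeder pair. Quasi-binomial (presence) and
quasi-Poisson (counts where ≥ 1) GLMs take the network factor plus raw
pair distance in metres (per-metre effects are the natural reporting
scale here, so no standardization). The dispersion is Pearson χ²/df;
the network term's analysis of deviance divides its deviance reduction
by the dispersion on 2 df; McFadden's pseudo-R² is computed on the
unscaled likelihood against the intercept-only model. These are
standard GLM computations and are delegated to statsmodels.

## The synthetic-data generator

The generator mirrors the fitted model rather than simulating mechanistic
movement: per species × pair × season cell, presence is Bernoulli on the
logit scale with the zero-part coefficients and feeder effects
`u_a + u_b`; given presence, `1 + Poisson` birds of that species
participate, each contributing a zero-truncated Poisson count with the
count-part coefficients, feeder effects, and its own tag effect. This
makes parameter recovery a well-posed experiment — the estimand is
exactly the generating coefficient vector. Mechanistic realism
(territoriality, dominance, daylight) is deliberately out of scope, so
passing tests demonstrate correct inference under the model's own
assumptions, not robustness to behavioural misspecification.

Default conditions emulate the field design: three ~0.5 km² networks,
17 feeders each placed uniformly with a 40 m minimum spacing (mean
nearest-neighbour spacing ≈ 81 m), two ringing sites ~15–25 m from a
feeder, 150 tags per network at a 2:1 blue:great tit ratio, 2 m rasters
with Gaussian canopy blobs (the vegetation index co-varies with height
so bare ground stays below the index threshold), and street segments
whose per-network counts (3/4/8) put total road-gap counts in the
low-hundreds per 136 pairs, the range reported for comparable urban
study areas. Per-network blob/road scale factors create a
fragmentation gradient (more vegetation and fewer roads in the "low"
network). Default generating coefficients follow the sign pattern of
published feeder-network analyses: vegetation positive, distance and
road gaps negative, seasonal offsets against a summer baseline, a
negative great-tit contrast; variance components
σ²_feeder = 0.5 (zero part) / 0.3 (count part), σ²_tag = 0.3.

**Rendering and the exact round trip.** Each truth connection is
rendered as a pair of visit bouts (1–5 reads, 20 s apart) with an
inter-bout gap drawn log-uniform between 1 min and a per-season budget
cap (≤ 40 h); a tag's consecutive connection slots are separated by
more than the 48 h cutoff, so the only consecutive-bout candidates that
survive extraction are the intended ones and the extracted
per-pair-season count table equals the truth table *exactly*. The
spacing rule bounds one tag's connections per season at ~40; the
simulator caps draws at that capacity (the cap is lifted in recovery
runs, which fit the truth tables directly and render nothing). A
configurable fraction of slow (> 48 h) transits is injected in leftover
time to exercise the discard path, and tags with no connections
contribute single-feeder nuisance visits that produce bouts but no
events.

## The recovery experiment

`feedernet.recovery` fixes one landscape design — 30 feeders, 136
sampled pairs, 4 seasons × 2 species, 150 tags, the middle fragmentation
scales so road-gap classes are balanced and vegetation is not
saturated — and redraws the hurdle outcomes 200 times, refitting both
parts each time. Generating coefficients for recovery keep the field
sign pattern at magnitudes ≥ 0.3 on the standardized scale, so a
relative-bias summary is resolvable at a few hundred replicates. The
zero part is compared on the standardized scale (its grid is complete,
so the fitted scale equals the generating scale); the count part is
compared on the raw covariate scale, because its rows are selected by
the zero process and within-sample standardization differs from the
generator's — the back-transform is an exact linear reparameterization
of the ML optimum, with the covariance mapped through the full
Jacobian. Observed performance (200 replicates): every coefficient of
both parts within 10% relative bias, Wald CI coverage 0.92–0.97.

## Numerical choices and problem sizes

- Ellipse-line intersection uses a 256-segment polygonal approximation
  only for road tests; pixel membership uses the exact ellipse equation.
- Zero-truncated sampling uses inverse-CDF conditioning
  (`ppf(F(0) + u·(1 − F(0)))`), stable at both small and large rates;
  likelihood code uses `expm1` throughout and clips η to ±30.
- All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning; identical configurations give
  byte-identical outputs.
- Test-suite problem sizes: full synthetic studies run at the field
  scale (3 × 17 feeders, ~45k detections, ~8k connections); round-trip
  checks use 20 compact 6-feeder studies; the recovery experiment uses
  200 replicates of the 1,088-row zero-part grid plus its count rows
  (~2–4k). These sizes resolve the stated tolerances while keeping the
  whole suite in a few minutes.

## Known limitations

- The Laplace approximation (both parts) and Wald CIs; no profile
  likelihood, no REML-like correction, no adaptive quadrature (the
  multi-membership structure precludes it).
- `σ²_d` for the truncated family uses the untruncated-rate
  approximation.
- The renderer's slot spacing means rendered studies cannot express more
  than ~40 connections per tag per season; heavier traffic is capped.
- The generator shares one coefficient vector across networks; network
  differences arise through landscape covariates and scale factors, not
  per-network coefficient sets (configure per-network runs for that).
- No home-range or trajectory modelling between feeders, no
  graph-theoretic summaries beyond degrees/totals, no spatial
  autocorrelation structures.
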