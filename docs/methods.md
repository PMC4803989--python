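# Methods

## Model and pipeline

The package implements the exposure-based comparative risk assessment
chain for long-term ambient ozone and COPD:

station measurements → interpolated exposure surface → per-cell relative
risk → population attributable fraction (PAF) per region → attributable
DALYs.

### Coordinates and distance

All locations are WGS84 lon/lat in decimal degrees. Distances are
great-circle kilometres via the haversine formula with Earth radius
6371.0088 km. At national scale this avoids committing to any map
projection; interpolation weights depend only on distance, so the choice
matters more than the raster's nominal projection. Rasters are
cell-centre addressed regular lon/lat grids, exchanged as ESRI ASCII —
a human-readable format that round-trips bit-exactly at a declared
precision (6 significant digits by default) and needs no binary
dependency. Region maps must share the exposure grid's spec exactly;
resampling is out of scope.

### Interpolation

**IDW.** Ẑ_j = Σ w_i Z_i / Σ w_i, w_i = d_ij^(−p). The power p defaults
to 2 — the conventional choice — and all stations participate (no
search neighbourhood); both are configurable. A target within 1e−9 km
of a station returns that station's value exactly, making IDW an exact
interpolator; predictions are convex combinations, hence bounded by the
data range.

**Ordinary kriging.** The semivariogram is estimated by the classical
Matheron estimator, γ(h) = (1/2N(h)) Σ (Z_i − Z_k)², over pairs binned
by haversine distance — 12 equal-width bins to half the maximum pairwise
distance by default (standard geostatistical practice), empty bins
dropped. A bounded model (spherical by default; exponential and
Gaussian available, both using the "practical range" convention
1 − exp(−3h/r)) is fitted by weighted least squares with Cressie
weights N(h)/γ_model(h)², nugget constrained ≥ 0, via a four-point
multi-start trust-region search over (nugget fraction, range fraction)
∈ {(0, 0.3), (0, 0.8), (0.2, 0.5), (0.5, 1)} of the empirical variance
and maximum lag. Prediction solves the (n+1)×(n+1) ordinary-kriging
system with a Lagrange multiplier, so weights sum to one; with zero
nugget the predictor is exact at stations. Duplicate station
coordinates are an error (naming the colliding stations) rather than
being averaged — this keeps the exact-interpolator property testable.
Grid prediction factorises the station-side system once and solves all
cell right-hand sides together. Numerically negative kriging variances
are clamped to zero with a warning.

Fewer than three retained variogram bins raises an error instructing an
IDW fallback rather than guessing a model.

### Cross-validation

LOOCV predicts each station from the remaining n−1 and scores the
(measured, predicted) pairs with MAE, RMSE and Pearson r (two-tailed p
from the t distribution). The variogram is refitted on every fold by
default — the honest LOOCV — with a flag to reuse one pre-fitted model
when speed matters. Folds that fail (unfittable variogram, singular
system) are recorded and excluded from the metrics with a count, not
silently dropped; zero-variance prediction vectors yield an undefined
r, reported as NaN. Model comparison ranks by RMSE then MAE and
expresses the accuracy gap relative to the worse model,
100·(worse − better)/worse.

### Health impact

RR = exp(β·Δx) with Δx = max(x − x₀, 0). β defaults to ln(1.040)/10 per
ppb: the slope implied by a cohort relative risk of 1.040 per 10 ppb of
long-term ozone for COPD, the source used by GBD-style assessments.
This calibration reproduces the six published regional RRs of the Thai
reference setting within ±0.01 (checked in the test suite before the
default was frozen). Δx is floored at zero: concentrations below the
TMRED contribute no excess risk — negative excess risk is not
meaningful under a log-linear risk function.

The TMRED is a band, 33.3–41.9 ppb by default. Two collapse policies
are provided: `midpoint` (37.6 ppb; deterministic, the default) and
`uniform_average` (average the per-cell PAF contributions over K = 100
evenly spaced counterfactuals across the band; by convexity of the
exponential this is slightly larger than the midpoint result).

Pe_i is the cell's share of the national population aged ≥ 25, a single
national age fraction applied uniformly. Pe is normalised **nationally**
(Σ Pe_i = 1 over the whole study area), so a regional PAF
S_R/(S_R + 1), with S_R = Σ_{i∈R} Pe_i(RR_i − 1), reads as a fraction
of the *national* COPD burden. Consequences: the national PAF weakly
dominates every regional PAF, a one-cell region reduces exactly to the
single-category form pe(rr−1)/(pe(rr−1)+1), and with spatially constant
RR the national PAF equals that single-category form at pe = 1.

### Burden attribution

AB = PAF × TB. By default TB is the **national** COPD DALY total for
every region, consistent with the nationally normalised PAFs (the
published regional burdens of the reference setting satisfy
AB_region ≈ PAF_region × national COPD total); the alternative
convention (regional PAF × regional COPD total) is available behind
`against_national=False`. The male/female split applies one national
ratio — the national male share of COPD DALYs — uniformly across
regions. All arithmetic is carried in full precision; DALYs are rounded
half-up to integers only at the report boundary, so the regional rows
can disagree with the Total row by a DALY or two, and the conservation
checks allow ±2.

## Synthetic data

The generator emulates the structure of the Thai study setting, not its
chemistry:

- **Concentration field**: a Gaussian random field with a specified
  variogram, drawn by dense Cholesky factorisation of the covariance
  C(h) = sill − γ(h) on all cell-centre pairs (with escalating jitter
  up to 1e−6 if needed). Exact and simple, but O(n³): grids are capped
  at 4,000 cells. Defaults: spherical variogram, partial sill 200 ppb²
  (field sd ~14 ppb, matching the dispersion of the reference kriging
  surface), range 300 km, nugget 0, mean 100 ppb — so excesses over the
  37.6 ppb TMRED midpoint land in the 43–85 ppb range of the reference
  setting. Negative draws are clipped at 0 and counted.
- **Stations**: 52 by default, split 28/10/2/8/1/3 across the six
  regions (urban-heavy Central, one Western station, as in the emulated
  network), placed population-weighted within regions, with 5 ppb
  Gaussian measurement noise so LOOCV metrics are non-degenerate.
- **Population**: a mixture of isotropic Gaussian kernels plus a 10%
  uniform floor, scaled to sum exactly to the requested total.
- **Regions**: a Voronoi partition of the grid around six random seed
  cells — irregular contiguous regions without any polygon machinery.
- **Burden table**: regional DALYs proportional to regional population,
  scaled to the published national totals (COPD 259,512 DALYs; male
  share 204,312/259,512; 10.2 M total DALYs).

`make_scenario` also computes **ScenarioTruth**: regional PAFs and ABs
evaluated directly on the true field, bypassing interpolation, so a
pipeline run's error isolates the interpolation stage. Truth is
invariant to station sampling and noise by construction.

What the generator does **not** emulate: seasonal/diurnal ozone cycles,
chemistry-transport structure, anisotropy, coastlines or irregular
study-area masks, spatially varying age structure, and regional sex
ratios. Passing recovery tests therefore demonstrate statistical
correctness of the pipeline under a smooth isotropic field with known
covariance — not predictive validity on real monitoring data.

## Problem sizes and numerical choices

The recovery suite runs 20 seeded scenarios on a 30×40 grid (1,200
cells, 0.25° cells spanning roughly the latitude range of Thailand)
with 52 stations — large enough for stable variogram estimation and
regionally resolved PAFs, small enough that the dense-Cholesky draw and
per-fold variogram refits stay cheap. On these scenarios the
kriging pipeline recovers regional PAFs with a mean relative error
well inside the ±15% bound asserted in the tests, and kriging's LOOCV
RMSE is below IDW's on average, mirroring the reference comparison.

Tie-breaks and degenerate inputs: coincident target/station within
1e−9 km returns the station value (first match wins); all pairwise
distances equal collapses the variogram to a single bin; an all-zero
semivariance (pure nugget) is an explicit error; a zero national
population is an error; Pearson r on zero-variance vectors is NaN with
the pairs still reported.

## Known limitations

- Single pre-averaged concentration per station; no per-year
  interpolate-then-average variant.
- Isotropic variograms only; no universal/co-kriging.
- No uncertainty propagation into the DALY table (point estimates
  only, matching the reference report's layout).
- Short-term (daily) ozone effects are out of scope by design.
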