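# Methods

## Scope and design

`montrange` is organised as a pipeline of seven stages, each usable on
its own: synthetic world generation, occurrence curation,
mountain-cohort selection, suitability modelling, dispersal buffering,
scenario projection, and range accounting. The package's central design
decision is to pair the pipeline with a virtual-species world whose
truth is known — partly in closed form — so that the pipeline's
quantitative behaviour is testable. Everything below states the model
actually implemented, its defaults, and what the verification does and
does not establish.

## The synthetic world

**Terrain.** The DEM is a base elevation plus `n_ridges` anisotropic
Gaussian ridges (seeded centres, orientations, widths and amplitudes)
plus smooth noise, clipped at sea level. "Smooth noise" throughout the
generator is Gaussian white noise convolved with a Gaussian kernel
(default 3 cells), a two-parameter recipe for spatially correlated
("red") noise; smoothing shrinks the pointwise variance, so the `sd`
parameter is an upper bound. Mountain polygons are the dissolved cells
with elevation ≥ `mountain_elev_cut_m` (default 1000 m) — an elevation
cutoff, not a morphometric ruggedness criterion; it is enough to
exercise the area-fraction logic and is configurable.

**Climate.** bio1 (mean annual temperature) is
`T₀ − Γ·z/1000 − g·|φ − φ_ref|` plus smooth noise, with sea-level
temperature T₀ = 26 °C, lapse rate Γ = 6.5 °C/km, and a small poleward
gradient g = 0.3 °C/deg; bio12 (annual precipitation) rises
orographically (900 mm + 400 mm/km). The other eleven bioclim-like
layers are seeded linear mixtures of bio1, bio12, the DEM and an
independent smooth field, so the strong collinearity of real bioclim
stacks is present; nine soil-like layers are independent smooth fields.
With `noise_sd = 0` every layer is a deterministic function of the
terrain, which the closed-form oracles rely on.

**Scenarios.** A scenario ensemble warms bio1 by ΔT plus one
per-member draw (sd `gcm_spread_sd`, emulating between-model spread)
and scales the four precipitation layers; soil and the DEM are
unchanged, and the mixture layers deliberately keep their current
values (only the axes that carry the niches move). The three default
scenarios apply ΔT = 1.8 / 3.7 / 4.4 °C with precipitation scaling
1.02 / 0.95 / 0.90 and rising cropland pressure — end-of-century
magnitudes for a sustainability, regional-rivalry and fossil-fuelled
pathway respectively.

**Land use.** Per-cell class fractions are a logistic-normal field:
each class gets a baseline log-preference (natural classes favoured,
urban rarest) plus a smooth spatial field, and `crop_pressure` adds
log-mass to the nine crop/urban classes weighted by exp(−z/500 m), so
conversion concentrates in lowlands. Softmax across classes guarantees
the fractions sum to one per cell.

**Virtual species.** Suitability is a bivariate Gaussian in
(bio1, bio12): s(x) = exp(−(bio1−μ_T)²/2σ_T² − (bio12−μ_P)²/2σ_P²);
an infinite width disables an axis. The truth range is {s ≥ τ}
(default τ = 0.5). Presences are sampled without replacement from
truth cells with probability ∝ s^bias, jittered uniformly within the
cell, and given a uniform collection year ≥ 1981. Traits (growth form,
dispersal syndromes, juvenile period known for ~40% of species) are
drawn to mirror a herb-dominated flora in which animal dispersal is the
most and ant dispersal the least frequent syndrome.

The demo study uses 24 species with niche optima spread along the
elevation gradient, 120 presences each, on a 10° × 10° extent at 0.05°
(200 × 200 cells) — sizes chosen so the full study and its verification
complete on a laptop in seconds while leaving every mechanism
(thinning, percentile selection, CV folds, consensus votes) non-trivial.

## Curation and cohort selection

Cleaning applies filters in a fixed order and labels each rejected row
with its first failing reason: invalid coordinates, (0, 0) coordinates,
equal latitude/longitude, collection year before 1981 (inclusive rule:
1981 itself is kept, matching the climatology baseline; rows with no
year are rejected because the filter cannot be evaluated), outside the
region mask, outside the species' native mask. Thinning keeps exactly
one record per species per grid cell — the lexicographically smallest
(year, lon, lat, source) — a deterministic representative, so no
thinning seed is needed and results are independent of row order.

Mountain association buffers each species' records by 1 km, dissolves
the disks, and takes the fraction of that area inside the mountain
polygons. Buffers and areas are computed in a per-species Lambert
azimuthal equal-area frame on the authalic sphere (R = 6371.0088 km),
so km-unit buffers and km² areas are exact. The cohort is every species
with fraction strictly above the 75th percentile (linear-interpolation
quantile over the whole scored flora) and at least 14 occupied cells.

## The suitability engine

A deliberately fully-specified substitute for the usual
maximum-entropy toolchain: ridge-penalized logistic regression on
standardized linear + quadratic features, presence = 1 vs 10,000
background cells (demo study: 2,000) sampled uniformly with replacement
within the availability mask. Standardization constants come from the
background only, making fits invariant to affine predictor rescaling;
constant predictors are dropped with a warning. λ defaults to 1.0 and
is exposed in configuration; the intercept is unpenalized. The loss is
strictly convex, and damped Newton iterations run to a gradient norm of
1e−8 (with a full-step fallback near the floating-point plateau of the
loss), so a fit is a deterministic function of its inputs.

Evaluation: square spatial blocks (250 km edge; the longitudinal edge
widened by 1/cos of the mid-latitude) are assigned to five folds
greedily by descending presence count, each block to the currently
lightest fold — which bounds the fold-total spread by the largest
single block. AUC uses midranks (exactly the Mann–Whitney pairwise
statistic with half-credit ties). Folds without held-out presences or
background are skipped with a warning; fewer than two usable folds is
an error. Acceptance is mean fold AUC ≥ 0.70. The binarization
threshold (max sensitivity + specificity over observed scores, smallest
maximizer, computed with integer counts so ties break exactly) and
permutation importances (linear and quadratic features of a predictor
permuted jointly, AUC drop averaged over 10 permutations, floored at 0,
normalized) are computed on the full training data of the final model —
the engine binarizes one final model per species, not one per fold.

## Dispersal and projection

Per-generation maximum dispersal distance is
10^(base + form term + syndrome term) km from a shipped coefficient
table. **This table is synthetic**: it respects the documented ordering
unassisted wind < ballistic < ant < adapted wind < animal and
field-plausible magnitudes (0.01 km/generation for unassisted-wind
herbs up to ~1.8 km for animal-dispersed trees), and is recorded in
every run manifest so outputs are never mistaken for a published
trait-regression's. Species with several syndromes use the largest
distance; ferns are evaluated as wind-adapted herbs. Generations to the
2100 horizon are ⌊70 / juvenile period⌋, clamped to ≥ 1, with
growth-form means substituted for missing juvenile periods. The
reachable area is every cell whose centre lies within the total
distance (great-circle, via a KD-tree on unit-sphere coordinates) of a
current-range cell centre, intersected with occupied landmasses;
presences are always reachable, so the mask contains the current range
and is monotone in distance.

Projection per scenario: binarize each of the 5 members at the species
threshold, keep cells with ≥ 3 member presences, intersect with the
dispersal mask and with cells whose dominant land-use class (argmax
fraction, ties to the earliest listed class) is not among the nine
excluded crop/urban classes. The land-use mask applies to future ranges
only by default; `mask_current` exposes the alternative of masking the
baseline too. Missing member cells count as absence — conservative
presence calls.

## Accounting

Cell areas use the exact spherical formula
R²·Δλ·(sin φ_N − sin φ_S) per row rather than a projection —
closed-form, no resampling error (a 0.05° equatorial cell is 30.9 km²).
Loss and gain are percentages of current area; net = gain − loss
exactly. A species with net change exactly 0 counts as a gainer, so
losers + gainers = cohort size; cohort percentages are rounded half-up
to integers, table-style. Elevation statistics are unweighted means
over presence-cell DEM values; latitude limits are presence-cell centre
extremes; species with an empty future range contribute loss = 100%
and no elevation shift. Richness maps are per-cell sums of binary
ranges; change maps are future − current; display clipping hides cells
with current richness ≤ `clip_fraction` × cohort size (default 0.05,
with 0.10 the documented alternative). Proportional-loss maps divide
species lost per cell by species currently present, ignoring
expansions. Bootstrap CIs are seeded percentile bootstraps of the mean;
the group contrast is a pooled-variance two-sample t with
df = n₁ + n₂ − 2.

## Verification: what the oracles show

* **Closed-form upslope shift.** With zero noise, temperature-only
  niches, zero ensemble spread, no land-use exclusion and unlimited
  dispersal, a species' range is exactly the elevation band
  |T₀ − Γ·z/1000 − μ_T| ≤ σ_T·√(−2 ln τ), and warming by ΔT moves both
  band edges up by ΔT/Γ × 1000 m. The full pipeline (model fitting,
  thresholding, consensus included) reproduces the 307.7 m shift for
  ΔT = 2 °C within a few tenths of a percent. Because current and
  future ranges share one model and threshold, this checks the
  *projection* chain, not the niche estimate itself.
* **Niche recovery.** Accepted models recover the generating bio1
  optimum with a median absolute error of ~0.2 σ_T over 20 species.
  This experiment is deliberately run in its identifiable regime:
  a 1-D temperature-only niche (with several predictors co-varying
  along one gradient, the curvature split between their quadratics is
  unidentified — any split fits equally, and the ridge picks the
  minimum-norm one, corrupting single-predictor profiles), a smooth
  bio1 ramp with near-uniform availability, optima drawn inside the
  realized climate support, and a low sampling threshold (τ = 0.05).
  Each relaxation was measured to bias the recovered optimum: a
  mountain hypsometry skews availability toward warm values and pulls
  optima toward the sparse flank by up to ~1 σ_T; niches truncated by
  the support edge are unrecoverable in principle; a hard high τ
  truncates the presence process the quadratic likelihood assumes.
  These are real properties of presence–background estimation that
  users should expect on real data, not artefacts of this
  implementation.
* **Oracle equivalence.** The rank-based AUC and the max-SSS threshold
  agree exactly with brute-force pair counting and exhaustive scanning
  on 1,000 random heavily-tied instances.
* **Bootstrap calibration.** The 95% percentile bootstrap covers the
  true mean of N(0,1) samples (n = 50) in ≈ 95% of 1,000 replicates;
  the percentile method's slight undercoverage at this n (~0.94 true
  rate) is expected and visible under some seeds.

## Reproducibility

Every stage draws randomness from a child seed obtained by hashing the
master seed with the stage label (values < 2³¹, recorded in the run
manifest), so stages can be re-run in isolation and a full run is
byte-reproducible; the configuration, the dispersal coefficient table,
and every per-species rejection (infeasible sampling, below the
mountain threshold, AUC gate, empty range) are serialized into the run
directory.

## Known limitations

The generator does not attempt real geography, climate downscaling or
land-use economics; its value is statistical structure with known
truth. Passing the oracle suite shows the machinery is correct under
the generator's assumptions (Gaussian niches, suitability-weighted
sampling, additive climate change); it does not show that a quadratic
presence–background model is adequate for any real species, that the
synthetic dispersal table predicts real distances, or how the pipeline
behaves under the sampling biases of herbarium data beyond the ones
emulated (within-cell duplication, suitability-weighted collection).
Marginal single-predictor optima are not identifiable under strong
predictor collinearity, and niches truncated by the study region's
climate cannot be recovered — both affect real-data studies in the same
way. Percentages in cohort tables are integer-rounded half-up; with
small cohorts a one-species change moves them by many points.
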