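# Methods

This note records the models implemented in `paleodrivers`, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the limitations a user should keep in mind.

## Time and data conventions

Ages are in Ma before present and grow into the past; the present is 0.
A species is a pair (ts, te) with ts > te ≥ 0; te = 0 encodes an extant
species. "Alive at t" is half-open, te ≤ t < ts, so a species never
double-counts at its own origination age. Predictors live on a 0.1 Myr
age grid and are treated as piecewise constant within each grid cell
(the value at the cell's younger edge), both in the generator and in the
likelihood, so the two sides of a simulation study agree exactly.

## Birth–death with shifts (BDS)

Likelihood over a window [a, b):

    log L = Σ_births log λ(ts_i) + Σ_deaths log μ(te_i)
            − ∫_a^b N(t) (λ(t) + μ(t)) dt.

Events clipped at a window edge (ts ≥ b, or te ≤ a) contribute exposure
but no event term; this prevents founders entering at the data's oldest
age — or events shared between adjacent windows — from being counted as
speciations/extinctions. The integral is evaluated exactly from the
piecewise-constant structure via a precomputed cumulative lineage-time
function.

Speciation and extinction have independent shift-point structures, and
since the likelihood factorizes the two sides are sampled by independent
reversible-jump chains. Moves per iteration: log-scale multiplier update
of one rate level (probability 0.35), uniform slide of one shift age
(0.20), birth of a shift (0.225) and death of a shift (0.225). A birth
draws the new age uniformly over the window and a fresh level for the
*older* sub-interval from the prior; a death removes a shift and keeps
the *younger* level. With the birth level drawn from its prior, the
acceptance ratio reduces to (likelihood ratio) × ν/(k+1) for a birth and
(likelihood ratio) × k/ν for a death, where ν is the Poisson prior mean
on the shift count. The `prior_only` fit mode switches the likelihood
off; the chain then reproduces the Poisson(ν) shift-count distribution
to within Monte-Carlo error, which the test suite uses as a detailed-
balance check of the transdimensional moves.

Priors: shift count ~ Poisson(0.5) per rate (sparse by default — a shift
must earn its place), levels ~ Gamma(2, 2) (mean 1 event/Myr, weakly
informative for invertebrate-like rates), shift ages ordered-uniform.
Proposal scales are tuned toward ~30% acceptance during burn-in only
(fixed afterwards, keeping the chain Markovian). Burn-in is 20% of
generations; rate summaries (pointwise median and 2.5/97.5 percentiles
on a 1 Myr grid) use retained post-burn-in samples only. Medians rather
than means limit the influence of outlier samples.

## Multivariate birth–death (MBD)

Exponential links keep rates positive:

    λ(t) = λ0 exp(Σ_j Gλ_j x_j(t)),   μ(t) = μ0 exp(Σ_j Gμ_j x_j(t)).

Predictors are interpolated to the 0.1 Myr grid, log10-transformed
(after an automatic positivity shift of 1 − min when a series touches
zero or below — e.g. temperatures in °C) and z-scored, so coefficients
are comparable across predictors. The exposure integral uses midpoint
quadrature on the same 0.1 Myr cells; with the piecewise-constant
predictor convention this reduces exactly to the BDS likelihood when all
coefficients are zero.

Horseshoe shrinkage: Gj ~ N(0, l_j² τ²), l_j ~ half-Cauchy(0, 1),
τ ~ half-Cauchy(0, 1), one global scale per rate side. Scales are
updated by the inverse-gamma auxiliary-variable scheme, in which every
conditional is inverse-gamma with constant shape; the sampler therefore
consumes pre-generated random variates and is a deterministic function
of its seed. The shrinkage weight ω_j = 1 − 1/(1 + l_j²) summarizes
support; under the prior ω = sin²θ with θ uniform on (0, π/2), so its
prior median is exactly ½ and "mean ω across replicates > 0.5" (strict)
is the significance rule. Scale variables are clamped to [1e-12, 1e12]
purely against floating-point underflow in the l² ↔ ν recursion when a
coefficient sits at zero.

Coefficients are updated by per-coordinate Gaussian random walks
(scales adapted during burn-in), plus — every third iteration — an
independence refresh drawn from the conditional prior N(0, l_j² τ²),
accepted on the likelihood ratio alone. The refresh is what keeps the
chain mixing across the horseshoe's collapsed (l ≈ 0) and released
regimes; without it the prior itself is not sampled correctly. Baseline
rates use log-scale multiplier proposals with a Gamma(1.1, 1) prior
(near-flat at the origin on the rate scale).

Replicates: one chain per jittered lifespan table. A replicate whose
posterior, prior or likelihood trace has an effective sample size below
100 is re-run with 3× and then 6× the configured generations before
being excluded; pooling averages the per-replicate posterior-mean
weights and effects with equal replicate weights. ESS uses
n / (1 + 2 Σ ρ_k) with Geyer's initial-positive-sequence truncation of
the autocorrelation sum; a constant trace maps to the 0 sentinel
(always excluded).

Default chain settings are desk-scale: 200 000 generations, sampling
every 100, 20% burn-in. The tests and the acceptance script run 30 000
to 80 000 generations on datasets of roughly 300–2000 species, which the
convergence diagnostics show is ample at these problem sizes; all
settings scale up through `MBDSettings`/`RunConfig` unchanged.

## Windowing and MAPE

Windows are half-open [a, b). clip_to_window drops species without
overlap, clips spans to the window and flags which endpoint events are
observed inside it. The windowed analysis fits the MBD model
independently per window (fresh baselines, coefficients and shrinkage
per window); the full-frame analysis fits once over the whole span.

Rate agreement with the BDS baseline is scored per 1 Myr step as
|BDS − MBD| / BDS, using the pooled BDS posterior-median curve and each
replicate's MBD median curve (replicate-matched errors; the alternative
of pooling MBD medians first is a one-line change in
`build_mape_report`). Age-level MAPE is the median across replicates;
window and overall MAPEs are medians of the age-level values in scope
(a two-stage median; even counts use the midpoint convention). Steps
where the BDS rate is zero are undefined and excluded rather than
clamped — a percentage error against zero has no meaning. The
windowed-vs-full table re-slices the full-frame age-level errors into
the same windows, so both columns describe identical age sets.

## Predictor engineering

* **TRI** (terrain ruggedness): per cell, the Riley definition —
  square root of the summed squared elevation differences to the up-to-8
  land neighbours; sea neighbours are ignored. Reported as the mean over
  all land cells or over listed cells (the "cells containing fossil
  occurrences" mode).
* **Landmass shape**: area = land-cell count × cellsize²; perimeter by
  marching-squares contour tracing at the 0.5 level of the land mask
  after Gaussian pre-smoothing with σ = 0.8 cells. Raw marching squares
  on a binary mask overestimates a disc's perimeter by ~6.6% (staircase
  bias); the smoothing brings a 60-cell disc to +1.2% and a 40-cell
  square to −1.7%, which is what the shape tolerances in the tests
  reflect. Island holes and multiple landmasses are summed.
* **Shoreline development** D = P / (2√(πA)), 1 for a circle; **TCI** =
  D × TRI, in TRI units (metres), 0 for flat terrain, equal to TRI for a
  circular outline.
* **Geographic distance**: mean great-circle (haversine, R = 6371 km)
  distance over all unordered locality pairs in a 1 Myr slice; slices
  with fewer than two localities yield NaN, later filled by linear
  interpolation from neighbouring slices (logged).
* **Basin statistics**: number of distinct occupied basins and their
  mean area, each basin counted once per slice.
* **Diversity**: mean lineage count across replicates on the 0.1 Myr
  grid. With lifespans as inputs, any occurrence-level correction for
  sampling heterogeneity is already baked into the lifespans; the
  trajectory here is the raw lineage count.
* **Elevation**: the default statistic is the mean local relief (3×3
  neighbourhood max − min) at listed cells; a mean-elevation variant is
  provided because summary tables of this kind are often ambiguous
  between the two readings.
* Degenerate (constant) series standardize to all zeros with a warning
  instead of dividing by a zero standard deviation.

## Synthetic data

The generator mirrors the inference model: founders enter at t_start,
daughters bud off (the mother persists — the taxic convention of
species-level fossil work), and event times come from thinning a
dominating constant-rate process, which is exact because rates are
piecewise constant per 0.1 Myr cell. A configurable cap on the
instantaneous rate turns runaway-coefficient mistakes into a clear error
instead of an explosion. Replicate jitter adds truncated Gaussian noise
to ts and te (resampled until ts > te > 0; te = 0 is kept exact, since
extant status is certain). Elevation grids are analytic shapes (disc,
square, composite) with iid Gaussian roughness, carrying their true
area/perimeter as ground truth; localities follow a per-lineage Poisson
process, clustered on land cells, with basin ids given by cluster.

What it does *not* emulate: preservation and sampling (lifespans are
taken as known up to jitter, with no occurrence-level inference), spatial
speciation dynamics, autocorrelated replicate uncertainty (the jitter is
independent across species and replicates), or realistic palaeogeography
(grids are geometric shapes). Passing recovery tests therefore show that
the inference machinery works when its assumptions hold; they say
nothing about preservation-driven biases in real data.

In simulation studies the clade starts slightly before the analysis
window (t_start = 105 Ma for a [0, 100) window) so that founders never
sit on the window edge, where replicate jitter would otherwise push a
random half of them inside as spurious birth events.

## Known limitations and open choices

* The BDS likelihood applies no survival/sampling conditioning; with
  data generated by the matching process this is exact, but fits to real
  data inherit whatever conditioning the upstream lifespan inference
  used.
* The horseshoe construction (unit half-Cauchy scales, one global scale
  per rate side) is a standard choice; other hyperprior scales would
  shift the exact ω calibration.
* MAPE measures agreement with the BDS *estimate*, not with truth. When
  the baseline cannot resolve a rate excursion (few events, short
  excursions), a reconstruction that tracks the truth can score worse
  than a flat curve; the windowed-vs-full test therefore uses a
  sustained in-window signal that the baseline demonstrably recovers.
* Windows are fixed and non-overlapping; no model averaging across
  window schemes, no interaction terms or confounder adjustment.
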