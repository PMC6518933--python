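# Methods

`pondscape` analyses biodiversity change in a two-epoch pond metacommunity:
a landscape of shallow saline ponds surveyed once in the 1950s and again
around 2010, after roughly 70% of the ponds had been lost. The question the
pipeline answers is whether the species that disappeared are only what
random removal of habitat would predict (a sampling effect), or whether the
surviving ponds themselves lost species — the signature of disrupted
colonisation–extinction dynamics after the habitat network thinned out.

## Data model

Three plain CSV tables (comma-separated, UTF-8, `.` decimal, empty cell =
absent): a pond table (planar coordinates in metres, per-epoch area in ha
and annual-mean conductivity in mS/cm, extant/sampled flags), one site ×
species incidence matrix per epoch, and a species body-size table (mm).
Conductivity doubles as the habitat-quality proxy: in these ponds it is
tightly correlated with pH, turbidity, depth and trophic state, and it is
the only abiotic variable measured in both epochs. Species traits are
derived, not supplied: occupancy is the fraction of epoch-1 *sampled* sites
occupied (the sampled matrix, not the full pond census, is the trait
denominator), preference is the mean conductivity of occupied epoch-1
sites, and regional extinction means absence from the pooled epoch-2
species list.

## Rarefaction null

Sample-based rarefaction gives the sampling-only expectation. Each of
`n_runs` (default 2000) accumulation runs is a uniform random permutation
of the sites — resampling is without replacement; a bootstrap would mix
scales. Expected richness at `m` sites has the closed form

    E[S_m] = Σ_i [ 1 − C(n − n_i, m) / C(n, m) ]

(`n_i` = sites occupied by species i), evaluated with log-gamma; the
Monte-Carlo machinery is kept because only it yields envelopes and the
area axis, and the closed form cross-checks it in every run of the test
suite.

On the site-count axis the central curve is the per-`k` mean and the
envelope the exact empirical 2.5th/97.5th percentiles (type-7
interpolation) — quantile regression would only approximate what discrete
`k` gives exactly. On the continuous area axis, the pooled (cumulative
area, richness) points of all runs are fit by quantile regression at
τ = 0.025, 0.5, 0.975 on a clamped cubic B-spline basis (`qr_df` = 5 basis
functions, interior knots at quantiles), each fit minimising pinball loss.
The central area-axis estimate is the τ = 0.5 fit; the median is robust and
uses the same machinery as the bounds. Quantile crossing is resolved by
sorting the three curves pointwise. No extrapolation: a target outside the
observed cumulative-area range is an error. Expected loss is γ minus the
central curve at the target, rounded to the nearest integer for reporting;
the area-axis confidence band is intrinsically wide because pond areas span
orders of magnitude, so runs reach a given total area with very different
site counts.

## Habitat number vs habitat area

For each accumulation run we ask which predictor — number of sites or
cumulative area — better explains the richness curve. Both enter one
additive model as penalized cubic regression splines (basis size `k` = 10,
reduced when x has fewer distinct values). The penalty is the second
divided difference of the spline coefficients taken with respect to the
Greville abscissae, so the null space is exactly the linear functions of x
(raw index differences would penalise linear trends near clamped
boundaries). Smoothing parameters minimise GCV, `n·RSS/(n − edf)²`, on a
log grid (joint grid for the two-term model). Within a run the two
predictors are strongly collinear — cumulative area is a noisy monotone
function of site count — so a term's importance is its drop-one loss of
explained deviance: the full model's explained deviance minus that of the
model without the term, each model's smoothing refit. The larger importance
wins the run; |difference| < 1e-10 is a tie (never broken arbitrarily) and
ties are excluded from the reported percentage. Because smoothing is refit
per model, drop-one deviance is non-negative only up to GCV selection
noise; small negatives are clipped to zero and logged. The working
likelihood is Gaussian: within a run the accumulation curve is
near-deterministic, and the contest compares fits, not inference.

The degenerate case of exactly equal site areas makes cumulative area an
affine function of site count; both submodels then explain the same
deviance and runs end in ties — the correct answer, since the data cannot
distinguish the predictors.

## Habitat network

The connectivity measure is closeness on the complete Euclidean graph of
*all* extant ponds in an epoch (116, then 30 — not just the sampled ones):
index(v) = mean distance from v to every other pond, in km. Direct edges
are shortest paths under the triangle inequality, so this equals the
all-pairs shortest-path mean (the graph-algorithm oracle in the tests).
The mean — rather than the farness sum or its reciprocal — keeps the index
comparable between networks of different size, which matters because the
temporal change Δcloseness = index_2010 − index_1957 (positive = the pond
became more peripheral) is the connectivity-loss predictor downstream. No
distance threshold is imposed: for passively dispersing zooplankton a
complete distance-weighted graph is the minimal assumption.

## Diversity change

α is per-site richness, γ regional richness, and β = γ / mean(α)
(multiplicative Whittaker partition). The between-epoch effect size D̄ of a
statistic is the absolute difference of the two group values (group mean
for α; one β per group — site-level pairing is not defined when the site
sets differ). Significance comes from permuting the pooled site rows into
groups of the original sizes (53 and 30 in the study's dimensions,
preserved in every permutation; 200 permutations by default), with
p = (1 + #{D̄_perm ≥ D̄_obs}) / (n_perm + 1): two-sided by construction and
never exactly zero.

## Driver models

Regional: logistic regression (IRLS, tolerance 1e-8, max 100 iterations)
of extinction on sqrt(occupancy), log(body size) and preference. The square
root spreads the many-rare occupancy distribution; the log makes body size
scale-free. A standardized slope exceeding 15 in magnitude flags
quasi-separation and marks the fit non-converged. Constant responses and
designs with condition number above 1e10 are errors.

Explained variance is partitioned by three-set commonality analysis: fit
all seven predictor subsets, convert each deviance pseudo-R²
(1 − D_res/D_null) with the Ezekiel adjustment
(1 − (1 − R²)(n − 1)/(n − p − 1)), and apply the standard commonality
algebra (pure_A = R(ABC) − R(BC), etc.). The seven fractions sum to the
full-model adjusted R² identically; individual fractions may be negative
under the adjusted convention. A variance-function pseudo-R² (squared
correlation of response with fitted probabilities) is available behind
`r2_variant="variance"`; published partitions of this kind often use a
variance-function R², so exact numeric parity with any particular report
is not expected from the deviance default. Local: the same partition with
Gaussian models (OLS adjusted R²) of the per-pond richness change at ponds
sampled in both epochs on Δcloseness, Δconductivity and Δlog-area (log is
the scale-appropriate default; `area_transform="identity"` is available),
plus one multiple regression for slope t-tests, raw p-values, no
multiplicity correction. The Gaussian partition is cross-checked against
`vegan::varpart` (R) in the test suite; the implementation itself never
calls R.

## Synthetic landscape generator

The generator exists so the whole pipeline is testable, and parameter
recovery demonstrable, without external data. It emulates the study's
structure, with every stage a pure function of (params, seed):

* **Landscape** — 116 ponds uniform on a 27 × 10 km rectangle (≈270 km²);
  areas lognormal(meanlog 2.0, sdlog 1.2) ha (median ≈7.4 ha, right-skewed,
  2010 totals in the few-hundred-ha range); conductivities
  lognormal(0.8, 0.6) mS/cm (mean ≈2.7, matching the ~3 mS/cm typical of
  these ponds).
* **Species pool** — 60 species; baseline prevalence Beta(0.35, 1.6)
  (many rare, few common); Gaussian niches on log-conductivity, sd 1.0,
  optima uniform on [ln 0.5, ln 8] mS/cm. Occupancy is an independent
  Bernoulli with p = prevalence × niche factor; species never observed are
  dropped.
* **Habitat loss** — exactly 30 survivors; uniform subset by default, or a
  clustered mode where survival odds fall logistically with distance from a
  random focal point (Gumbel-max weighted sampling keeps the count exact).
  53 epoch-1 ponds are marked sampled, 24 of them survivors, mirroring the
  study's sampling. Surviving ponds shrink (lognormal factor, meanlog −0.3,
  sdlog 0.3) and drift saltier (Gaussian, mean +0.77, sd 2.0 mS/cm, floored
  at 0.05) — the drift mean and spread match the observed mean increase and
  local range of conductivity change.
* **Relaxation** — each surviving incidence flips to absent independently
  with probability logistic(b0 + b_conn·Δcloseness + b_area·Δlog-area +
  b_cond·|Δconductivity|); defaults b0 = −2.0, b_conn = 0.8 /km,
  b_area = −0.3, b_cond = 0.15 /(mS/cm). Extinction acts per incidence, not
  per species: regional extinctions emerge from erosion of occupied sites,
  as observed. There is no recolonisation (a `no_extinction` flag gives the
  null world); adding colonisation dynamics is out of scope. b_conn was
  calibrated so that the pure Δcloseness fraction recovered at 24 shared
  sites averages ≈0.2 across landscapes — the magnitude of the published
  effect this generator emulates — which also makes the effect reliably
  recoverable (the generator's design target).

What the generator does **not** emulate: taxonomic drift between surveys,
seasonal pooling, spatially autocorrelated environments, dispersal kernels,
abundance structure (incidence only), or observation error in either
epoch. Passing tests therefore demonstrate that the estimators recover
known structure under the model's assumptions, not that those assumptions
hold in any particular field system.

## Numerical choices and degenerate inputs

Penalized solves add a relative ridge of 1e-9 and use a pseudoinverse:
with collinear predictors the two smooths share an unpenalized linear null
space and the normal matrix is singular. GCV grids are logspace(−5, 9, 29)
for single smooths and logspace(−4, 8, 9) per term (81 combinations) for
the additive model. QuantReg pools up to 100k points (subsampled above
that, seeded). Constant-richness envelopes short-circuit to constant
curves. `expected_loss_sites` at m = n returns exactly 0 (every permutation
ends at γ). Permutation p-values compare with a 1e-12 slack so exact ties
count as exceedances. Seeds: one master seed is split per stage via
`SeedSequence(master, spawn_key=(stage,))`, all derived seeds < 2³¹.

## Problem sizes

Default analyses use 2000 accumulation runs for rarefaction and 200
permutations, as in the study's design; the predictor contest uses 500
runs by default in the scripts (each run refits three GCV-selected spline
models, which dominates cost; the winner percentage is a binomial
proportion whose standard error at 500 runs is already below one point).
The test suite's property checks use 20 random toy matrices for the
rarefaction oracle, 1000 replicates at 200 permutations for calibration,
50 landscapes for parameter recovery, and 500 shuffled-response runs for
the null contest.

## Known limitations

* The drop-one deviance importance is one defensible reading of "which
  smooth term matters more"; AIC- or significance-based contests could
  rank runs differently. The winner percentage is decision-sensitive.
* The deviance pseudo-R² partition is not numerically identical to
  variance-function-based partitions; both are provided, one is default.
* Closeness is one of several connectivity variants (farness, reciprocal,
  thresholded graphs); the mean-distance form is chosen for cross-epoch
  comparability, and regression coefficients on Δcloseness are specific to
  that choice.
* Areas and conductivities are treated as error-free; the epoch-1 survey's
  partial seasonal coverage is assumed harmonised upstream.
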