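# Methods

This note documents the statistical machinery, its assumptions, the
defaults that matter, and the choices made where the design was open.

## Co-occurrence null model

The unit of analysis is a binary site × species occupancy matrix,
restricted to sites where at least one species occurs (presence is
abundance strictly greater than zero; the data this emulates enumerate
live and dead individuals together, and no live/dead split is modelled).

For a species pair with occupancy counts r_i, r_j and S shared sites, the
checkerboard units are CU = (r_i − S)(r_j − S); the C-score is the
arithmetic mean of CU over all unordered pairs. The null hypothesis is
tested against the *fixed–fixed* (SIM9) ensemble: all binary matrices with
the observed row and column totals, weighted uniformly. We sample it with
the swap chain — an elementary move draws two distinct rows and two
distinct columns uniformly and, if the 2×2 submatrix is a checkerboard,
flips it; non-checkerboard draws are no-ops that still advance the
attempt counter. Because the proposal is symmetric and every move is its
own inverse, the stationary distribution is exactly uniform; the test
suite verifies this against exhaustive enumeration of a 3×3 marginal
class, and the full null distribution against R vegan's `quasiswap`
sampler (an independent exact fixed–fixed algorithm).

Chain defaults: burn-in 30,000 elementary attempts; thinning equal to the
number of matrix cells; 5,000 replicates from a single chain; all from one
integer seed. The standardized effect size is
SES = (observed − null mean)/null SD with the sample (n−1) SD; the 95%
limits are empirical 2.5/97.5 percentiles of the replicates; tail
p-values count ties as extreme (conservative).

Pairwise tests harvest every pair's CU from the same chain. A pair is
called non-random only when two criteria agree: (a) its observed CU,
standardized by its own null mean and SD, falls outside confidence limits
built from the pooled distribution of all pairs' null-standardized scores
(an empirical-Bayes-style pooling), and (b) its own tail p-value is below
α (default 0.05). Positive SES with both criteria → *segregated*;
negative → *aggregated*; otherwise *random*. A Benjamini–Hochberg
adjustment over the per-pair two-sided p-values is reported alongside.
With three species the pooled distribution rests on only three pairs;
the pooling is a documented approximation to the legacy Fortran
implementation of the empirical-Bayes pair analysis, whose exact decision
rule is not public.

### Degenerate marginals

If every row sum equals one, no 2×2 checkerboard exists and every matrix
in the ensemble shares the same pair counts: the null SD is zero and the
SES is reported as NaN with a warning rather than a fabricated value.
This is why meaningful pair tests need richness variation among sites.

## Environmental gradients

Site covariates (moisture, conductivity, pH, organic C, total N,
elevation, distance to coast, microbial biomass and richness, other-fauna
counts) are strongly collinear, so models use principal components of the
z-scored covariate table (equivalently, eigenvectors of the correlation
matrix). Axes are kept up to the smallest leading prefix reaching 2/3 of
total variance (configurable). Missing values are mean-imputed within
column with a warning; constant columns are dropped by name. The sign
convention makes each axis's largest-magnitude loading positive. Aspect
enters the occupancy models as a dummy-encoded factor (most frequent
level as reference), not through the PCA.

## Spatial structure

**Moran's I** uses binary distance-class weights (default ten
equal-pair-count classes) with two-sided permutation p-values from
randomizing site labels.

**Spherical correlation**: corr(d) = (1 − nugget)(1 − 1.5h + 0.5h³) with
h = d/range for d < range, exactly zero beyond the range, and corr(0) = 1.

**PCNM / db-MEM**: the truncation distance t is the longest edge of the
minimum spanning tree of the Euclidean distance matrix; distances beyond
t are replaced by 4t; the truncated matrix is double-centred as in
classical PCoA; eigenvectors with positive eigenvalues are kept, centred
and scaled to unit norm. On a regular transect the leading vectors are
sinusoids of increasing frequency, which the tests verify.

**Forward selection** of spatial vectors minimizes a multivariate AIC,
AIC(k) = n·log(RSS_total/n) + 2·m·(k+1), where RSS_total pools residual
sums of squares over the m response columns and the parameter penalty is
paid once per response column. The per-column penalty is what keeps
greedy selection over a pool of ~n/2 candidate eigenvectors parsimonious:
with the penalty paid only once, selection on pure-noise responses picks
dozens of vectors (the best of ~190 candidates essentially always beats a
penalty of 2), while the per-column form selects a median of zero vectors
on noise and a handful on structured data. Ties break to the lower vector
index; the selection path (vector, AIC) is recorded and is strictly
decreasing. Selection uses the Hellinger-transformed abundances as the
response, matching the ordination it serves.

## Spatial binomial occupancy regression (PQL)

Each species' presence is regressed on the gradient axes, the aspect
factor and the other species' presence indicators. The fitting scheme is
penalized quasi-likelihood with a spherical residual correlation:

1. at the current linear predictor η form the working response
   z = η + (y − μ)/(μ(1−μ)) and weights w = μ(1−μ);
2. update β by generalized least squares with covariance
   diag(1/√w) · R(θ) · diag(1/√w), R the spherical correlation of
   inter-site distances;
3. estimate θ = (range, nugget) from the empirical semivariogram of the
   Pearson residuals.

Two numerical safeguards matter in practice and are deliberate design
choices:

- **Staging.** The iid fit (R = I, plain IRLS) is converged first; θ is
  then estimated from its residuals and the GLS fit re-converged with θ
  fixed, for at most three outer rounds. Co-evolving θ and β from
  scratch is unstable — a transiently long-range correlation estimate
  amplifies the working response at near-certain sites and the iteration
  diverges.
- **Deviance-guarded steps.** Each scoring step is accepted only if it
  does not increase the binomial deviance, halving up to ten times
  otherwise; a direction with no acceptable step terminates the loop at
  the current iterate. Un-damped GLS scoring on binary data with extreme
  fitted probabilities can overshoot arbitrarily. A linear predictor
  exceeding ±40 after damping is treated as complete separation and
  raised as an error.

The variogram fitter uses equal-width lag bins up to one quarter of the
maximum separation (range information lives at short lags; far bins only
contribute single-realization fluctuation), weights bins by pair counts,
profiles the range over a grid with the nugget and partial sill solved by
non-negative weighted least squares at each candidate, and polishes the
best point locally. The range is constrained to the binned lags — beyond
the largest lag it is not identifiable. If the fitted partial sill is
under 2% of the total, the spatial term is dropped (R = I). The nugget
proportion is capped at 0.9 to keep R well conditioned; coincident sites
are jittered by 10⁻⁸ m.

Standard errors come from the GLS information matrix (binomial dispersion
fixed at 1); t statistics use n − p degrees of freedom. With the range
sent to zero the fit agrees with ordinary logistic regression to 10⁻⁴,
which the tests check against an independent implementation. Estimating
the correlation from residuals is a transparent approximation to
profiling θ inside PQL; coefficient estimates are expected to agree with
joint-REML implementations only approximately.

## Ordination and variance partitioning

Abundances (individuals per kg dry soil) are Hellinger-transformed
(square root of row-relative abundances; nonzero rows then have unit
Euclidean norm), making Euclidean least squares appropriate for species
count data. RDA column-centres the response, regresses it on the
predictor matrix, and takes the principal components of the fitted
values; R² = SS(fitted)/SS(centred response); overall significance by
permuting predictor rows (999 by default, seeded).

Variance partitioning computes the Ezekiel-adjusted R²,
1 − (1 − R²)(n − 1)/(n − m − 1), for all seven non-empty unions of the
three predictor sets (abiotic gradients, biotic gradients, selected
spatial vectors) and decomposes by inclusion–exclusion into three unique
fractions, three pairwise shared, one triple shared, and a residual; the
eight fractions sum to one by construction. Adjustment is essential here
because the predictor sets differ greatly in size; its price is that
shared fractions can be slightly negative, which are reported as-is and
flagged, never truncated. Gradient axes are assigned to the abiotic or
biotic set by which variable group dominates their squared loadings.

Residual correlations are Pearson r between species' RDA residual
columns with two-sided t-tests. Note that Hellinger rows are
norm-constrained, so residuals of a dominant species are compositionally
pushed toward negative correlation with the others; the planted-truth
simulations are the control for how much of an observed negative r is
interaction versus closure.

## Synthetic landscapes

The generator emulates the Dry-Valleys study design so that every stage
of the chain can be tested against known truth:

- **Sites**: 314 points uniform over a 20 × 11 km planar domain (the
  surveyed occupied-site count and a domain of the study's extent).
- **Gradients**: Gaussian random fields with spherical covariance,
  range 4.5 km (the radius at which the real correlograms lose
  structure), sill 1, nugget 0.1. Four "measured" axes (wet/saline,
  topographic, microbial, fauna) plus one unmeasured field per species
  (`disp_*`, coefficient 0.8 on log-abundance) standing for dispersal /
  mass-effect processes: spatially structured abundance variation that
  leaves no trace in the covariate table and can therefore only be
  captured by the spatial eigenvectors — the study system's central
  feature.
- **Covariate table**: raw variables are noisy linear mixtures of the
  latent axes (moisture negative on the wet/saline axis; conductivity,
  pH, C, N positive; elevation and distance-to-coast on the topographic
  axis; biomass/richness on the microbial axis), giving the PCA stage
  realistic collinearity to compress.
- **Occupancy**: species are drawn in a fixed order (Scottnema,
  Eudorylaimus, Plectus); logit p = intercept + gradient terms + γ ×
  (presence of earlier species). Conditional DAG-ordered generation is
  exactly simulable and produces the checkerboard structure the null
  models must detect; it is not a joint Markov-random-field model, a
  documented simplification. Intercepts are calibrated by root-finding
  so expected occupancies hit 289/222/50 of 314. The `mdv_like` preset
  plants γ(Sc→Pl) = −2.25 and γ(Sc→Eu) = γ(Eu→Pl) = +1.2 logits,
  matching the magnitudes the occupancy models report for this system;
  `null` removes all interactions and gives each species its own
  environmental driver; `env_only` produces segregation purely from
  opposing responses to a shared moisture gradient — the central
  confound the analysis chain must distinguish from true interaction.
- **Abundance**: where present, zero-truncated negative binomial
  (variance μ + μ²/k, dispersion k = 1.5) with log-mean following the
  same gradients. Truncation keeps the abundance and occupancy views
  exactly consistent.

Determinism: one config seed is expanded through `SeedSequence.spawn`
into independent streams for sites, fields, covariates, occupancy and
abundance, so changing one stage's parameters never shifts another's
draws. The pipeline does the same per analysis stage.

### What passing tests do and do not show

The generator reproduces the *structure* of the study system — spatially
autocorrelated collinear gradients, rare-versus-common species, planted
segregation and aggregation, spatially structured abundance variance
independent of measured covariates. It does not reproduce the real
data's signal-to-noise: explained-variance fractions on `mdv_like`
(total ≈ 17–20%, pure-spatial ≈ 5%) are well below the published
percentages for the real assemblage, and no attempt was made to match
them by tuning noise levels. Recovery results on synthetic data
therefore validate the estimators, not the field study's effect sizes.

## Known limitations

- The pairwise empirical-Bayes pooling approximates a legacy program
  whose internal decision rule is unpublished; with only three pairs the
  pooled limits are coarse.
- PQL coefficient estimates with estimated correlation are approximate;
  the spherical parameters are identified only up to the binned lags,
  and single-realization variograms of strongly autocorrelated fields
  can mis-state the range by tens of percent.
- Cross-species coefficients from conditional (non-joint) logistic fits
  carry small-sample bias when one species is rare (~50 presences);
  single-fit estimates scatter with SD near 0.8 logits, which is why
  recovery checks average over replicate landscapes.
- Coordinates are assumed planar-projected metres; geographic input must
  be projected upstream.
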