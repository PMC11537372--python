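# Methods

This note documents the statistical models, the synthetic-data generator and
the numerical choices behind `disaggval`, in the order the pipeline runs
them.

## Survey statistics

A survey location is 1–4 quadrants of 100 m × 100 m (δ = quadrants ×
10,000 m²). The unweighted response `A_C` is the summed area of monoculture
fields, intercropped fields and individual-plant discs (radius 0.5 m, area
π/4 m² each) divided by δ; the weighted response `A_CW` multiplies each
field's area by a weight mapped from its qualitative density class and
down-weights intercropped fields by 0.75. The class weights are VeryHigh
1.75, High 1.5, Regular 0.75, Sparse 0.5, VerySparse 0.25; fields with no
recorded class get 1.0. That "Regular" sits below "unrecorded" is an
idiosyncrasy of the published weighting table that we reproduce verbatim
rather than smooth over. Individual plants are never density-weighted —
their contribution is a measured count times a fixed disc.

Both responses are reported as proportions (the survey's estimand is the
proportion of the study area under cassava) alongside unnormalized m²
components, which is what cohort descriptive tables conventionally print.
Quartiles everywhere use linear interpolation between order statistics
(`numpy.quantile` default). A location counts as a "50:50 split" when its
intercrop share of fields lies strictly between 40% and 60%; the cutoff is a
package choice, as no standard exists.

## Raster extraction

A cell belongs to a buffer when its **center** falls within the radius —
the common raster-extraction semantics; partial-cell area weighting is out
of scope. Missing cells are excluded from all statistics and `n_cells`
counts only used cells; an empty zone yields missing values with a warning,
never a silent drop. The standard deviation uses the n−1 denominator.
Binary settlement layers admit only the mean (the settled fraction);
requesting anything else is an error rather than a meaningless number.
Synthetic scenes use a planar CRS in metres; geographic rasters are
supported through a local equirectangular metric (adequate for ≤ 10 km
radii away from the poles).

## The regression engine

All smooths are penalized cubic B-spline regressions: equally spaced knots,
basis dimension k = 10 per 1-d smooth (shrunk to at most n − 2 for small
samples), k = 5 per margin for 2-d tensor products, with a second
**divided**-difference penalty built at the Greville abscissae. The divided
(rather than plain) differences matter: the penalty's null space is then
exactly the affine functions of the covariate, so an infinitely penalized
smooth collapses onto the ordinary straight-line fit and heavily penalized
GAMs agree with their linear-model counterparts to rounding error. Each
smooth absorbs a sum-to-zero constraint over the observed data into its
basis, keeping the intercept identifiable.

Smoothing parameters minimize GCV by default, with the
degrees-of-freedom cost inflated by γ = 1.4 — the standard guard against
GCV's well-documented tendency to undersmooth, without which null fits on
permuted coordinates routinely absorb noise. Restricted likelihood (REML)
is available as an alternative (`method="REML"`). One smoothing parameter
uses bounded scalar search; several use Nelder–Mead on log λ from two
starts. The effective degrees of freedom is the trace of the hat matrix;
the Gaussian log-likelihood is evaluated at the ML variance RSS/n, matching
ordinary least squares exactly when no smooth is present.

## The factorial model search

Six responses (total / monoculture / intercrop density, unweighted and
weighted) are each regressed on one cassava map variable — production or
harvested area, at the point or buffered at 2/5/10 km under one of seven
summaries — under one of four forms: linear, logarithmic, quadratic, or
spline. The log offset c is half the minimum non-zero covariate value
whenever zeros are present, else 0. Quadratic terms use orthogonalized
polynomial columns to avoid collinearity. Population covariates add the same
distance × summary structure with forms linear / log / independent spline /
dependent 2-d spline; settlement covariates likewise but restricted to the
mean summary; optionally a joint 2-d spline over population and settlement.
When a dependent 2-d spline with the cassava variable is requested, the
tensor absorbs the cassava main effect. Point extraction always has summary
= mean.

A model's type is derived from its forms — any smooth term makes it a GAM,
otherwise it is a linear model — so a fully parametric specification is
fitted once, not twice under two labels. The enumerator deduplicates and
reports its count; `expected_space_size` gives the closed-form product for
any restriction, which the tests check against the enumeration.

Information criteria support two conventions: "standard"
(AIC = −2·logLik + 2p, BIC = −2·logLik + log(n)·p) and "as_printed"
(−logLik + 2p / −logLik + log(n)·p, a variant that appears in print). For
models of equal parameter count the two can never disagree on ordering —
both are decreasing affine functions of the likelihood — which is asserted
as a property test. p is the OLS rank for linear models and the total
effective degrees of freedom (intercept included) for GAMs. Adjusted R² is
1 − [RSS/(n−p)]/[TSS/(n−1)]. Non-converged fits (degenerate designs,
factorization failures) stay in the results table with missing criteria so
the downstream screen sees the unbalanced design honestly.

## The AIC screen

Each converged model contributes one row: AIC as response; model type,
cassava type / distance / summary, population and settlement inclusion and
their nested distance / summary factors as treatments. Distances become
categorical labels; absent covariates take a single "none" level on their
nested factors. The treatment model is

    modeltype * (cass_type * population_type * settlement_type
                 + cass_type * cass_dist * cass_summary
                 + population_type / population_dist * population_summary
                 + settlement_type / settlement_dist)

with `/` the usual nesting expansion. Because the design is unbalanced and
partially confounded, type-II F statistics are computed by
marginality-respecting model comparison: each term's sum of squares is the
rank-aware RSS drop from adding it to the model holding every term that
does not contain it. Containment uses a nesting closure — the nested
distance / summary factors implicitly carry their inclusion factor — since
otherwise the "none" level of a nested factor aliases the inclusion effect
exactly and the screen could never report it. Wholly aliased terms are
reported with df = 0, not silently dropped. On full-rank designs the
results agree with `statsmodels.anova_lm(typ=2)` to 1e-8 (asserted in
tests); the in-package route exists because standard implementations do not
handle deliberately aliased screening designs gracefully.

## Spatial trends and regional contrasts

Trend models fit log(response + ε₀) ~ s(longitude) + s(latitude) with
independent smooths and no interaction — road-transect surveys cannot
support a full 2-d surface, and formal geostatistics is excluded for the
same reason. ε₀ is half the minimum positive response when zeros are
present, mirroring the covariate-offset rule. The same model applies to
dissolved-buffer raster extractions, so survey and map trends can be
compared curve against curve. Smooths are exported on 100-point grids with
Bayesian pointwise standard errors. Regional contrasts use one-way ANOVA of
the square-root transformed response across administrative regions
(F with df = regions − 1, n − regions); the square root stabilizes the
heavy right skew of per-location areas but deliberately breaks shift
invariance, which a test documents by counter-example.

## Association analyses

Spearman correlations use average ranks for ties and pairwise-complete
observations; constant variables produce missing coefficients with a
warning. A two-country layout places one country's coefficients above the
diagonal and the other's below. Presence/absence contrasts report
five-number summaries of each prediction layer by group, with an optional
Wilcoxon rank-sum statistic labelled exploratory.

## The synthetic scene generator

The generator is first-class, tested code; its defaults are the study
conditions, not tuning knobs.

* **Population**: exp(μ + σ·G) with G a unit Gaussian random field with
  exponential covariance (range 20 km on a 120 km × 120 km grid of 1 km
  cells), simulated by circulant embedding — exact up to truncation of the
  embedding's small negative eigenvalues. μ = 3, σ = 1 give right-skewed,
  spatially coherent densities.
* **Settlement**: population above its 0.7 quantile (strict), a ~30% settled
  fraction; the threshold is the quantile, so `settlement_threshold = 1.0`
  yields an empty mask.
* **Regions**: Voronoi cells of seed points drawn from the survey locations
  themselves — any labelled partition would do, and seeding from locations
  guarantees every region is surveyed, making the regional-ANOVA df
  structure (8, 60 and 3, 83 for the two study designs) a property of the
  design rather than luck.
* **Production**: within each region a fixed total (proportional to region
  size with lognormal variation) is allocated to cells proportionally to
  population^e (e = 1; e = 0 severs the population link for null
  experiments). The published map is this allocation convolved with a
  uniform disc of radius `displacement_m` (cultivation happens near, not at,
  habitation; default 2 km) and multiplied by cellwise lognormal noise with
  the link noise sd. **Harvest area** is production times a smooth field in
  (0, 1).
* **Surveys**: locations every 15–20 km along random road-like transects;
  1–4 quadrants (mostly 4); presence with probability 0.75 (0.87 for the
  87-location design). For present locations the true cassava proportion is
  inverse-logit(−2 + 1.5·z + noise), z standardizing the *clean* allocation
  — at the point by default, or averaged over `link_scale_m` when the truth
  is defined at neighbourhood scale. The proportion is partitioned into
  lognormal-sized fields (median ≈ 150 m², log-sd 1.2 — highly
  right-skewed, as real field-size data are), management intercropped with
  probability 0.45, density classes drawn from a 5-point distribution with
  20% unrecorded, and 0–10 individual plants.

Because truth references the clean allocation while the published raster is
displaced and noisy, point extraction is a degraded predictor while buffered
means recover the signal — the pipeline's buffered-beats-point finding is
therefore testable as *recovery of a known mechanism*. The acceptance tests
run this experiment over ten seeds with displacement = link scale = 2 cells
and every location present: absent locations respond zero regardless of any
covariate, so including them only dilutes the contrast the experiment is
designed to isolate.

What the generator does **not** emulate: real road networks (transects are
straight), land-cover constraints on cultivation, temporal dynamics,
GPS/measurement error in field perimeters, and the empirical marginal
distributions of any real population or crop map. Passing tests therefore
demonstrate that the estimators recover the structure they target under a
plausible generative mechanism — not that any particular real map is
accurate.

## Problem sizes and persistence

The default test-suite scenes are 50–120 cells square with 20–87 locations;
the restricted factorial spaces span 8–600 models. These sizes keep a full
run of suite plus acceptance script in a few tens of seconds while leaving
every factor of the screening design estimable. Rasters persist as
single-band GeoTIFF (float64 inside scenes, so write → read round-trips are
exact; float32 available for general export), surveys as GeoJSON
FeatureCollections, truth and configuration as CSV/JSON, with sha256
checksums in a manifest; scene regeneration and persistence are
byte-deterministic under a fixed seed.

## Known limitations

* GCV/Nelder–Mead smoothing selection is deterministic but only
  tolerance-reproducible under row permutation (~1e-5 on smooth estimates).
* The local equirectangular metric for geographic rasters degrades near the
  poles and for buffers ≫ 10 km.
* The tensor-product basis uses equal k per margin and no main-effect
  decomposition (no ti()-style separation of main and interaction effects).
* The "as_printed" information-criterion convention changes values, not
  equal-p orderings; cross-p orderings can differ between conventions, which
  is inherent to the definitions.
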