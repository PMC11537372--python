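# disaggval

Validation of crop-production **disaggregation maps** against ground surveys.

Disaggregation models distribute coarse (sub-national) crop production totals
onto a ~1 km grid using covariates such as rural population density. Whether
such maps are trustworthy at local scale can only be checked against field
surveys. `disaggval` implements the full validation pipeline for this
comparison — built around cassava surveys of the kind run in sub-Saharan
Africa (roughly 200 m × 200 m survey locations spaced along motorable roads,
with per-field management and planting-density records) — together with a
synthetic scene generator so every stage runs end-to-end with no data
download.

## What it computes

**Survey statistics.** For each surveyed location the proportion of land
under cassava,

    A_C  = (Σᵢ αᵢ + Σⱼ βⱼ + Σₖ γₖ) / δ

where αᵢ are monoculture field areas, βⱼ intercropped field areas, γₖ the
disc areas of individual plants (0.5 m radius) and δ the surveyed area; and a
density-weighted variant

    A_CW = (Σᵢ ωᵢ αᵢ + 0.75 · Σⱼ ωⱼ βⱼ + Σₖ γₖ) / δ

with weights ω mapped from qualitative density classes
(VeryHigh 1.75, High 1.5, Regular 0.75, Sparse 0.5, VerySparse 0.25,
unrecorded 1) and intercropped fields down-weighted by 0.75.

**Raster extraction.** Map predictions (production, harvested area), gridded
population and a binary settlement mask are extracted at the survey points
and summarized over 2/5/10 km circular buffers (mean, median, sd, min, max,
quartiles; binary layers admit only the mean), individually per location or
over the dissolved union of all buffers.

**Model search.** A factorial space of regression models links each survey
response to the extracted summaries: every combination of map variable ×
buffer distance × summary statistic × functional form (linear, log with a
half-minimum-nonzero offset, quadratic, penalized spline), optionally with
population and settlement covariates (including 2-d tensor smooths). Each
model's AIC, BIC and adjusted R² are extracted, and the AICs are screened
with a type-II unbalanced ANOVA over the design factors to identify which
choices (model type, buffer distance, summary, covariate inclusion) drive
model quality.

**Spatial structure.** Directional trends — additive smooths over longitude
and latitude, fitted independently to the log response — for survey data and
for dissolved-buffer raster extractions; one-way ANOVA of square-root
transformed production across administrative regions; Spearman correlation
matrices and presence/absence contrasts between survey measures and map
predictions.

Smooth terms are penalized B-spline regressions (second divided-difference
penalty, GCV- or REML-selected smoothness) authored in `disaggval.gam`.

## Worked example

```python
from disaggval.synthetic_data import ivory_coast_like, generate_scene
from disaggval.survey_metrics import summarize_location, cohort_summary, response_table
from disaggval import geo_extract
from disaggval.geo_extract import BufferSpec
from disaggval.model_search import (SearchConfig, enumerate_model_space,
                                    fit_model_space, rank_models)

scene = generate_scene(ivory_coast_like(seed=1))   # 69 locations, 9 regions
summaries = [summarize_location(sv) for sv in scene.locations]
cohort = cohort_summary(summaries, scene.locations).set_index("statistic")["value"]
print(f"visited: {cohort['locations_visited']:.0f}, with cassava: "
      f"{cohort['locations_with_cassava']:.0f} ({cohort['presence_pct']:.0f}%)")

zonal = list(geo_extract.extract_points(scene.production_raster, scene.locations))
for d in (2, 5):
    zonal += geo_extract.zonal_summaries(scene.production_raster, scene.locations,
                                         BufferSpec(d), ("mean",))
data = response_table(scene.locations).merge(
    geo_extract.covariate_table(zonal), on="location_id")

space = SearchConfig(cass_types=("production",), cass_distances=(0, 2, 5),
                     cass_summaries=("mean",), include_population=False,
                     include_settlement=False, allow_joint_2d=False)
results = fit_model_space(enumerate_model_space(space), data)
ranking, best = rank_models(results)
print(ranking[["modeltype", "cass_dist", "cass_form", "AIC", "adj_R2"]].head(3))
```

prints

```
visited: 69, with cassava: 52 (75%)
modeltype  cass_dist cass_form         AIC   adj_R2
      gam          2    spline -135.390316 0.661193
      gam          5    spline -122.394178 0.579079
   linear          2    linear -117.474754 0.528738
```

75% of the simulated locations have cassava, and the best models by AIC use
the map *buffered* at 2 km rather than the point prediction — the buffer
averages out both the cell-level noise of the map and the spatial offset
between where people live (which drives the disaggregation) and where they
cultivate. That ranking is the package's central diagnostic: a map can fail
at its native resolution yet capture real large-scale variation.

A command-line interface mirrors the stages
(`disaggval simulate|metrics|extract|search|screen|trends|associate|run-all`);
`disaggval run-all --seed 1 --out run/` writes every stage's CSV plus a run
log to `run/`.

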