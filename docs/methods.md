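# Methods

## Scope and data model

`ecoshift` implements a complete ecosystem-suitability pipeline on
rectangular grids of square cells. A `GridSpec` fixes the geometry (rows,
columns, cell size, upper-left origin; row 0 is northernmost); a
`RasterLayer` is one named variable with a nodata mask; a
`PredictorStack` is an ordered set of layers on one grid with a shared
period tag, and a cell masked in any layer is masked for every
stack-level operation. Cells tile the plane half-open (a point on a
shared edge belongs to exactly one cell, by the floor convention on its
offset from the origin), and every stage that needs a representative
point for a cell uses the cell center. External interchange is plain
text: single-band ESRI ASCII grids plus a JSON manifest for stacks,
CSV with a JSON comment header for training tables, GeoJSON for
property polygons.

Terrain derivatives use the Horn 3×3 stencil with border and
nodata-adjacent cells masked rather than padded — the standard DEM
practice, and deterministic. Transformed aspect is the Roberts–Cooper
form `trasp = (1 − cos((aspect − 30°)·π/180))/2`,
spanning 0 (cool NNE slopes) to 1
(hot SSW slopes); the literal reading `1 − cos(·)/2`, whose range is
[0.5, 1.5], is kept behind a `literal=True` flag because it is
occasionally printed that way, but a 0–1 solar-load proxy is the form in
which the quantity is used and plotted. Pixel areas use a spherical Earth
(R = 6371 km): a 2.5-arc-minute cell at 39° N comes to 16.7 km², the
single constant-area figure used throughout; a per-latitude mode exists
for geographic grids where the cosine variation matters.

## Sampling design

Per ecosystem, plots are screened by *distinct grid cells with a
presence* (minimum 50). The pseudo-absence envelope is the union of
100-km disks around all records clipped to the study area — the text
that motivates it ties the envelope to per-record radii, so no convex
hull is taken (a hull variant exists for sensitivity checks). 2,500
points are drawn uniformly inside the envelope by seeded rejection
sampling; there is no climatic rejection and no exclusion zone around
presences, so an absence may fall within one cell (~4 km) of a presence,
and absences landing in suitable cells are an accepted source of label
noise. Dedup keeps one row per cell with presence priority and
lowest-plot-id tie-breaking; class sizes are *not* rebalanced. The
train/test split (default 80/20) is stratified by label with
round-to-nearest per-stratum counts, so 100 presences + 2,500 absences
yield exactly 80/2,000 train and 20/500 test rows; stratification keeps
both labels in the test set so AUC and Sørensen are always defined.

## Model

The problem is framed as regression of the 0/1 label on predictors,
optimised for RMSE, because the target quantity is a continuous
suitability score, not a calibrated class probability. Recursive feature
elimination ranks predictors by the permutation importance (5 repeats)
of a single 250-tree random forest fit on the training partition —
permutation is the conventional random-forest importance for regression,
and it proved far more stable than impurity importance under the
collinearity the generator deliberately produces — then measures
cross-validated RMSE (4 folds, 50-tree forests) of a refit on the top-k
subset for each size in {2, 4, 6, 8, 10, 12, 16, 22}, selecting the
argmin with ties broken toward the smaller subset. The fold and tree
counts are desk-scale choices, exposed in `RFEConfig`.

Four base learners — scikit-learn `GradientBoostingRegressor` (GBM),
XGBoost tree and linear boosters (XGBT, XGBL) and
`RandomForestRegressor` (RF) — are tuned over small fixed grids with one
shared, seeded, label-stratified 10-fold assignment so comparisons are
paired. The default grids are single modest settings (GBM 160 trees ×
depth 3, XGBT 250 × 3, XGBL 200 rounds, RF 280 trees) chosen to keep a
full seeded experiment at desk scale; `EnsembleConfig.tuned()` exposes
the wider search (trees 250/500 × depth 2/3 × learning rate 0.05/0.1)
when the extra wall time is justified, and `EnsembleConfig.fast()` a
reduced setting for smoke tests.

The combiner is an RMSE-based weighted blend of the base predictions,
clipped to [0, 1]: non-negative least squares fit of the label on the
out-of-fold base-prediction matrix, falling back to inverse CV-RMSE
weights in the degenerate all-zero case. A gradient-boosted meta-model
trained strictly on the same out-of-fold predictions is available via
`EnsembleConfig(combiner="stack")`. The weighted blend is the default
because a shallow tree meta-model emits piecewise-constant scores whose
heavy ties measurably degrade ranking quality (hold-out AUC drops
0.02–0.04 in our experiments) while leaving RMSE unchanged.

## Validation and importance

AUC is computed by the rank-sum identity (ties counted ½). Sørensen uses
the standard `2TP/(FN + 2TP + FP)` with range [0, 1]; the halved
`TP/(FN + 2TP + FP)` variant (range [0, 0.5]) is available as
`variant="as_printed"` for comparability with reports that print that
form — reported index values above 0.5 are only reachable under the
standard form, which is why it is the default. The binarization
threshold for the confusion counts defaults to 0.5, is configurable, and
is always echoed in the report. Performance screens AUC ≥ 0.75 and
SOR ≥ 0.5 are reported as boolean flags, not enforced.

Permutation importance permutes one predictor column n times (default
35, seeded), recomputes RMSE with all permuted copies batched into a
single prediction call, and reports the mean and SD of the increase over
the unpermuted baseline (also reported). Evaluation uses at most 1,000
rows (a seeded subsample, the conventional default of permutation
explainers; configurable, None = all rows). Partial dependence sweeps
one predictor over its observed range at a seeded background sample
(default 100 rows), averaging predictions at each sweep value.

## Shift and zonal metrics

Suitability-weighted area is Σ s·A over cells with s ≥ τ: the product
rule and the τ filter are combined deliberately, and the unweighted
variant (Σ A over passing cells) is emitted alongside for transparency.
τ defaults to 0.33 with a per-ecosystem override table (some rare
ecosystems are conventionally cut at 0.16), and a 0.5 preset serves
high-suitability bookkeeping. Elevation and northing shifts are
*unweighted* means of the position layer over passing cells, following
the literal description of the procedure ("filter, extract, mean");
suitability-weighted means were considered and rejected because the
source text does not state a weighting. Percent changes are reported
unrounded; integer rounding is presentation. Transition classes apply
the four band rules (future ≥ 0.5 & hist < 0.5 → high increase;
future < 0.5 & hist ≥ 0.5 → large loss; 0.25 ≤ future < 0.5 &
hist < 0.25 → moderate increase; future < 0.25 & 0.25 ≤ hist < 0.5 →
moderate loss) in order, else unchanged; swapping the two periods maps
gains onto losses exactly.

Zonal areas apportion each cell to a polygon by the fraction of the
cell's area inside it (shapely intersection), so properties near or
below the one-cell minimum are handled gracefully; a cell-center
membership mode exists for speed. Properties below 16.7 km² are tagged,
not dropped. Across scenarios, per-zone percent differences are
summarised by mean, sample SD, min, quartiles and max; at least two
scenarios are required.

## Synthetic landscapes

The generator emulates the *structure* of a mountain-west study system,
not any real region. Elevation is a broad gradient rising 1,200 m south
to north and 300 m west to east plus a smoothed Gaussian random field
with 700 m of relief (σ = 6 cells), floored at 50 m. Nineteen bioclimate
layers derive from four latent fields — mean temperature (sea-level
24 °C, lapse rate 6.5 °C/km, 12 °C south-to-north cooling, 2.5 °C smooth
mesoclimate noise), annual temperature range (16 ± 8 °C, its own spatial
structure, representing continentality), annual precipitation (250 mm
base + 0.12 mm per metre of elevation ± 120 mm), and precipitation
seasonality — plus per-layer noise. The monthly extremes load heavily on
the range latent (bio5 = T + 0.55·R) while the annual mean carries its
own 1.2 °C station-scale noise and the quarterly means track the annual
mean (loadings 0.05–0.15 of R, plus 3 °C of their own smooth noise), so
the temperature family is strongly collinear (pairwise correlations
with bio5 of roughly 0.8–0.93) but not degenerate.
Identities hold exactly: bio7 = bio5 − bio6 ≥ 0, and bio12 bounds every
quarterly precipitation layer. These couplings were dimensioned once so
that (a) the layers show the family-wise collinearity real bioclimate
variables have while the warmest-month maximum keeps enough distinct
variance to be identifiable, and (b) temperature varies along both
terrain and latitude, so warming has somewhere to push suitability.

Occurrences are presence-only: plot locations uniform over unmasked
cells, retained with probability equal to the truth suitability of their
cell. The truth intercept is *calibrated per landscape* (bisection) so
the ecosystem occupies a fixed fraction of the domain — rarity is a
design constant, not a by-product of the landscape draw. The default
experimental truth is a logistic in standardized bio5 (−7.5 per SD) and
elevation (+5.5 per SD) at 10% prevalence, i.e. a sharply
temperature-limited montane ecosystem — the regime in which real
analyses report high discrimination. Under this design the AUC ceiling
of the *true* suitability scored against the pseudo-absence labels is
≈ 0.92–0.95 (pseudo-absences landing in suitable cells bound what any
model can achieve), so held-out AUCs above 0.9 indicate the fitted
ensemble sits close to the attainable optimum. Scenarios add
offsets/factors to named bioclimate layers (never terrain, enforced)
with optional smooth noise; the uniform-warming helper shifts all seven
°C layers equally, preserving the range identity. Property polygons are
Voronoi cells of seeded random points clipped to the extent — a
non-overlapping, exhaustive tiling with state/ownership/agency
attributes.

What the generator does **not** emulate: real CMIP6 inter-model spread,
land cover, dispersal or disturbance, observation bias in plot
placement, and non-tiling, multi-part real property geometries. Passing
the recovery tests therefore demonstrates that the pipeline estimates
what it claims under its own assumptions, not that any particular real
ecosystem analysis is correct.

## Experiments and problem sizes

Two canonical studies (in `ecoshift.experiments`) define the conditions
under which the pipeline is exercised, at sizes chosen to run on a
single CPU in minutes:

* **Parameter recovery** — 100 × 100 grid of 4-km cells, 2,000 plots,
  default sampling (2,500 pseudo-absences, 100-km buffers), RFE over all
  22 candidates, default ensemble, 35-permutation importance (computed
  over the full table for ranking stability). Success per seed: held-out
  AUC ≥ 0.90, both true drivers in the RFE-selected subset, and both
  ranked top-2 by permutation importance.
* **Warming shift** — a purely temperature-limited ecosystem (logistic
  in bio5 alone, 12% prevalence) on a gradient-dominated landscape
  variant (600 m relief, 14 °C meridional cooling — gentler random peaks
  so the poleward signal is not drowned by which mountain happens to be
  tallest), uniform +4 °C, ensemble fit on all 22 predictors with a
  mid-size configuration (RFE is irrelevant to the *direction* of the
  shift); success per seed: mean suitable elevation and northing both
  increase at τ = 0.33.

The test-suite runs each over 20 seeds and requires 18 successes; the
acceptance script reports the same fractions over 10 seeds derived from
its `--seed` argument.

## Numerical choices and edge cases

Seeds: every stochastic step takes an explicit seed; multi-stage runs
derive stage seeds from one master seed via `numpy.random.SeedSequence`
(kept below 2³¹). Degenerate cases are errors, not silent defaults: 1×1
grids for gradients, per-latitude areas on projected grids, empty
envelopes, all-one-label tables, single-label AUC inputs, zero-baseline
percent differences, constant predictors in partial dependence, fewer
than two permutations or scenarios. RFE truncates oversized subset
requests with a warning. Boosted regressors can overshoot [0, 1], so
every prediction path clips. The dedup tie-break (lowest plot id) and
the sort-before-shuffle in the split make reruns bit-identical; the run
manifest records config hash, derived stage seeds and artifact
checksums so end-to-end reproducibility is checkable.

## Known limitations

Suitability is correlational: no dispersal limits, biotic interactions
or disturbance dynamics. Pseudo-absence geometry, not climate screening,
is the only control on label contamination, which caps attainable
discrimination (by design, as in the emulated procedure). The spatial CV
folds are random, not spatially blocked, so hold-out metrics are
optimistic in the presence of spatial autocorrelation — matching the
emulated procedure rather than current best practice. The ASCII-grid
interchange stores no CRS beyond a geographic/projected tag.
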