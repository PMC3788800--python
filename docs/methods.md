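# Methods

## The scoring model

Each group model is a weighted additive combination of modified factors.
For cell *c* with factors `f_ci ∈ [0,1]`, modifiers `m_ij ∈ [0,2]` and
weights `wᵢ > 0`:

```
MIS_c = normalize( Σᵢ wᵢ · normalize( f_ci · Πⱼ m_ij ) )
```

`normalize(x) = x / max(x)` over unmasked cells, with the convention that an
all-zero surface normalizes to zeros rather than raising — partial models in
the sensitivity analysis can legitimately zero a term, and the analysis must
still run. Two consequences follow directly from the final normalization:
MIS is invariant to scaling all weights by a common positive constant, and
the surface attains exactly 1 wherever any term is positive anywhere.

The model encodes *relative* importance within one landscape and season; the
absolute values are not comparable across models, which is why the exposure
analysis first converts every surface to quantile classes.

### Factor and modifier values

All class values live in `ModelConfig` and can be overridden per run (every
override is logged). The defaults are the published expert parameterization:

| quantity | default | units / notes |
|---|---|---|
| elevation modifier breaks | 2438, 2743 | m; classes 1 / 0.5 / 0.1, left-closed intervals |
| river proximity breaks | 5, 10 | km to streams of order ≥ 3; classes 2 / 1.5 / 1 |
| flyway modifier | 1.25 inside, 1 outside | mask supplied as a layer |
| wetland density ramp | 0.25 at 2/km², 1.0 at 28/km² | counts of wetland centroids per 5-km circular window; < 2/km² → 0, clamped at 1 above 28/km² |
| wetland size classes | 0 below 5 ha, 0.5 to 15 ha, 1 above | attribute-based, not geometry-derived |
| stream values (wetland/raptor) | large river 1, order 3–4 0.5, order 2 0.25 (wetland only) | "large river" is a feature flag, not a name lookup |
| stream values (riparian) | perennial order 2–7 → 1, intermittent → 0.25 | followed by 500-m decay |
| distance decay | v·min(1, (cell/d)²), zero beyond 500 m | inverse-distance-squared family; the source keeps its value at d = 0 |
| take-off/approach buffer | 1 km, carries source value, max-combined | around valued wetlands and valued streams |
| topographic position | standardized TPI > 1 in a 20- or 50-cell circular window | ridge/foothill/hogback factor |
| updraft match | same compass category 1, adjacent 0.75, else 0 | aspect classified into the same 8 categories as the wind grid |
| orientation (northness) | 2 − δ/90 with δ the long-axis deviation from north | minimum-area rectangle per stream feature / per ridge component |
| probability-index modifiers | 1 + index | cottonwood, willow, bare ground map [0,1] linearly onto [1,2] |

Notes on the open points these defaults settle:

* The decay family was named but not its formula; `v·min(1,(cell/d)²)` keeps
  the source value at distance zero and gives "some value" throughout the
  500-m reach. The `min` guard only matters for hypothetical sub-cell
  distances; on a grid, d ≥ cell size.
* Landform thresholds for the topography factor were not printed;
  standardized TPI > 1 (one SD more elevated than the window mean) is the
  common convention of TPI landform tools and is exposed as `tpi_threshold`.
* Interval closure: elevation and proximity classes abut, so boundaries are
  closed on the left (2438 m falls in the reduced class; exactly 5 km falls
  in the middle proximity class).
* Wind-versus-aspect matching treats the equality rule as category identity;
  whether the wind grid encodes direction blowing-from or blowing-toward is
  a property of the input layer and does not change the rule.
* Orientation is computed per feature: one northness value per stream
  polyline (applied along its footprint and through the 500-m decay reach,
  background neutral at 1), and one per connected component of the
  topographic-position factor. Single-cell ridge fragments have no axis and
  stay neutral.
* The density factor counts wetland representative points (centroids) so a
  polygon spanning several cells is not double-counted; sub-5-ha wetlands
  are excluded from the size factor but counted in density.
* The take-off/approach buffer extends around every wetland with a nonzero
  size value and every valued stream, carrying the source value.

## Validation chain

Occurrence records pass through: a species date-window filter (windows are
data, supplied as a `(species, start, end)` table); a positional-accuracy
filter (drop records with error worse than 400 m — the threshold direction
is an explicit option, `keep_worse_than`, because the rule is sometimes
stated invertedly); greedy 800-m thinning in descending quality order (kept
points are pairwise ≥ 800 m apart; the pass is idempotent); and stratified
subsampling of up to 10 points per species, warning below 50 points total.

The Boyce index ranks the surviving points by their MIS score, splits them
into k (default 10) nearly equal groups, and sets bin thresholds at the
midpoints of the scores straddling each split. Tied scores across a split
produce duplicate thresholds, which are merged — reducing the effective bin
count, the expected behavior on surfaces with a large zero mass. Bins with
zero area share are merged into their lower neighbor. The index is the
Spearman correlation between bin rank and point-share/area-share ratio; for
untied ratios it is computed with the exact classical rank formula so a
perfect ordering yields exactly ±1.

The permutation p-value is one-sided (positive association). It is exact
(full enumeration) for up to 8 effective bins and a seeded 10,000-draw
Monte-Carlo estimate above that, where full enumeration (10! ≈ 3.6M
orderings) buys no practical precision for a p-value on ten bins.

Expert scores are the mean over reviewers of (model rating × expertise),
with ratings on {−1, −0.5, 0, 0.5, 1} and expertise on {1, 1.25, 1.5, 1.75,
2}; the score spans [−2, 2] and zero separates poor from good models.

## Sensitivity and uncertainty

`enumerate_partials` produces one partial model per factor (term removed),
per modifier (removed from its term) and per non-unit weight (reset to 1) —
13 partials for the wetland model, 9 riparian, 7 raptor, 3 grassland.
Percent difference `100·|full − partial|/full` is computed over cells where
the full model is positive (the ratio is undefined at zero and no cap is
applied, so modifiers that redistribute mass can show SDs larger than their
means); its per-cell mean across partials is the uncertainty surface.
Classification accuracy quantile-classifies both surfaces into 5 bins
independently and reports the diagonal share of the cross-tabulation. SDs
here are population SDs (ddof = 0); the convention is not dictated by the
method and is stated so results are reproducible.

## Exposure overlay

Both surfaces are quantile-recoded: a cell's value is (number of quantile
breaks strictly below it)/(k−1), giving {0, 0.25, 0.5, 0.75, 1} for distinct
breaks. When ties collapse low quantiles (a zero mass spanning more than
20% of cells), the tied mass recodes to 0 and the surviving upper classes
keep their quantile values — the top 20% is always 1 and the top-two-quantile
mask (recoded ≥ 0.75) keeps its "top two classes" meaning. The exposure
surface is the cellwise product, classified very_low [0, 0.1), low
[0.1, 0.26), moderate [0.26, 0.56), high [0.56, 0.75], very_high (0.75, 1]:
the printed class bounds leave small gaps (0.259–0.26, 0.559–0.56) which are
regularized into this half-open cover so every attainable product
classifies. Under the multiplication rule two "high" cells give 0.75 × 0.75
= 0.5625 (class high) and two "low" cells give 0.25 × 0.25 = 0.0625 (class
very low) — note the low×low product is 0.0625, not the 0.125 sometimes
quoted for this construction; the multiplication rule is applied exactly.

Overlap statistics count cells: A = 100·|mig ∩ wind|/|mig| and
B = 100·|mig ∩ wind|/|wind| over the two top-two masks, so A·|mig| =
B·|wind| = 100·|∩| holds exactly. Uncertainty across the full and partial
models uses the per-cell population SD of exposure and a normal-approximation
95% CI (mean ± 1.96·s/√n) on the overlap percentages — with n = number of
model versions this CI is approximate, a stated limitation. A partial model
whose surface collapses to a constant has no quantile structure and is
excluded from the exposure ensemble.

## Synthetic landscapes

The generator emulates the *structure* the models consume, not any real
geography: an elevation surface built from a sloped plane plus anisotropic
Gaussian ridges (orientation mix between N–S and E–W is a parameter; ridges
are the only landform the generator guarantees, because the topography and
updraft factors need them); jittered stream trunks with branching
tributaries, orders 0–7, perenniality and a large-river flag assigned by
trunk depth; clustered wetlands whose log-uniform sizes span the <5 / 5–15 /
>15 ha classes and whose cluster spread varies so focal density crosses the
2/km² ramp threshold within one landscape; a correlated categorical
land-cover field covering the prairie, shrubland and riparian classes; 0–1
probability surfaces for cottonwood, willow, bare ground and prairie dogs;
a spatially coherent 8-category prevailing-wind grid; crops on the lowest
terrain; and a column-split flyway mask.

Defaults: 150×150 cells at 90 m (13.5 km square), 6 ridges with 70% N–S
orientation, 4 stream trunks, 5 wetland clusters of 220 wetlands (cluster
densities around wetland complexes must reach the 2/km² anchor for the
density ramp to engage — sparser defaults would silently zero the
heaviest-weighted wetland term), elevation 1500–3200 m so all three
elevation-modifier classes occur. Everything derives from one
`numpy.random.default_rng(seed)`; identical parameters and seed are
bit-identical.

Occurrence points are sampled with probability ∝ MISᵇ (b = 0 uniform), so
the per-cell expected count is n·MISᵇ/ΣMISᵇ — a known ground truth for the
validation chain. Dates fall inside synthetic per-species windows;
positional accuracy is log-normal (median ≈ 90 m, so the 400-m filter is
exercised) and quality ranks are uniform on 1–5. The wind-potential surface
mixes a squashed standardized-TPI component with an eastward gradient plus
correlated noise; `ridge_weight` controls how strongly it tracks ridges.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: hydrological realism (streams do not follow computed
flow paths), spatial autocorrelation structure of real occurrence databases
(observer effort, roads), correlation between wind potential and migration
drivers beyond shared topography, and any real geography. Pipeline Boyce
indices at the ~50-point validation size are correspondingly noisy across
seeds; the parameter-recovery property (ρ > 0.8 in ≥ 95% of seeds) is
established at n = 500 points where the estimator is stable.

## Problem sizes and numerics

The default landscape (150×150 cells) keeps a full four-group pipeline run
— models, 32 partials, validation, exposure — around a few seconds; factor
and modifier layers are memoized per (landscape, config) so each partial
model evaluation reduces to array products. TPI windows (20- and 50-cell
radii) follow the published tool settings and require grids of at least
101 cells per side. Focal density uses a KD-tree over wetland centroids;
distance operators use exact Euclidean distance transforms and are verified
against brute-force all-pairs oracles up to 50×50 in the test suite.
Quantile ties everywhere resolve by merging (value equal to a break falls
in the lower bin). Grids are plain-text ESRI ASCII rasters (NoData −9999)
and features GeoJSON; coordinates are projected meters with an upper-left
origin, and no reprojection or datum handling is attempted.
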