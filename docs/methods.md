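# Methods

This note documents the models, conventions and numerical choices behind
`beeload`, in the order data flow through the pipeline.

## Crosswalk keys

All joins run through controlled vocabularies: USDA crop name → USGS
crop group (one of ten: alfalfa, corn, cotton, orchards & grapes, other
crops, pasture & hay, rice, soybeans, vegetables & fruit, wheat),
compound name → CASRN → category and mode-of-action group, and crop
group → land-cover class code.  Join keys are normalized (upper-case,
trimmed, internal whitespace collapsed) because the source vocabularies
disagree on case and spacing.  CAS registry numbers are check-digit
validated at load (weighted digit sum mod 10) as a cheap guard against
hand-built-key typos.  California carries its own crop key because its
pesticide source data derive from a different reporting program covering
a larger crop list; the package routes California rows through that key
when one is supplied.  Acreage items are encoded in the key (harvested
acres for annual and hay crops, bearing & non-bearing acres for tree
crops), never inferred.

For double-crop land-cover classes the key lists the two component crop
groups **with surveyed components first**, plus a surveyed-component
count; this ordering convention is what lets downstream code know which
component of a half-surveyed double crop has an estimate.

## Consensus LD50

Endpoints are standardized to µg/bee, with exposure durations given in
hours converted to days (48 h → 2 d) before the acuteness filter.
Retained records are acute (≤ 4 days), adult, contact or oral.  The
resolution hierarchy is:

1. *Point estimates always beat censored bounds.*  Adding a ">x" or
   "<x" record to a compound with any point estimate never changes its
   consensus (a tested invariant).
2. Among points, regulatory (US-EPA / E.U.) estimates form the
   preferred tier when present; the consensus is the geometric mean of
   the tier, computed in log space (`exp(mean(log x))`) for
   overflow/underflow safety.  Regulatory estimates from the two
   jurisdictions are pooled in one tier rather than ordered — the
   narrative behind the preference rule supports either reading, and
   pooling uses more evidence.
3. With only bounds: the minimum of "<x" values if any exist
   (conservative — a lower LD50 means more toxic), else the maximum of
   ">x" values.  A compound with both bound kinds but no points takes
   the "<" rule and is flagged (`mixed_bounds`), since that case is not
   covered by the stated preferences.
4. Compounds with no usable endpoint receive the median consensus value
   of their mode-of-action group; if the group has no resolved member,
   the median over all resolved insecticides (falling back to all
   resolved compounds only when no insecticide is resolved at all).
   Imputing from an empty set is a hard error.  Medians use the
   midpoint-of-middle-two convention for even counts.

The resolution is deterministic and order-invariant (tested).  A
documented constant (`HONEY_BEE_WORKER_MASS_MG = 120`) supports users
who wish to rescale lethal doses to other bee species by body weight;
it is not applied anywhere.

## Crop-area panel

Census acreage is authoritative in census years (1997, 2002, 2007,
2012, 2017) even when a survey value coexists; the annual survey fills
other years.  Remaining interior gaps are filled by linear interpolation
between the nearest bracketing observations of the same state × crop
series.  There is **no extrapolation**: years before the first or after
the last observation stay missing, because one-sided fills are not
"between surrounding years".  Zero-area observations are valid anchors —
a crop can disappear from a state.  Acres convert to hectares with the
international acre, 0.40468564224 ha exactly.  Group aggregation sums
hectares within state × group × year and reports an
`interpolated_fraction` (share of group hectares contributed by
interpolated records) so users can judge reliance on interpolation;
crops absent from the key are excluded and returned by name, never
dropped silently.

## Rates and bee toxic load

Rates are simple quotients kg / ha per compound × state × group × year;
the use table's `low` estimate is the default variant (it tracks
independent estimates more closely), with `high` selectable.  Use rows
without a positive matching area are flagged and reported, not dropped;
missing use rows are treated as "no data", not zero, because survey
missingness and true non-use are indistinguishable in the source.

Bee toxic load divides each insecticide's rate by its consensus LD50.
The kg → µg bridge is exactly 1e9; "lethal doses per hectare" is
dimensionally forced once rates are kg/ha and LD50s µg/bee.  Loads sum
across insecticides only (fungicide/herbicide LD50s are still produced
for users who wish to extend the sum).  Compound-level rates run through
2017; aggregate loads truncate at 2014 by default because seed-applied
pesticides — a dominant contributor to bee toxic load — are excluded
from the source data after that year (`max_year=None` overrides).
Interior gaps in aggregate load series are interpolated per measure
independently (kg/ha, contact doses/ha, oral doses/ha), flagged
`interpolated=True`.  No synergy between compounds is modelled; the sum
is strictly additive.

## Reclassification and mapping

A reclass table maps each land-cover code of one state-year to its crop
group's value.  Double crops are additive (pesticide use on a
wheat/soybean double crop = wheat value + soybean value).  Missing data
conventions follow the table kind: the **aggregate** table reports a
double-crop value only when both components have estimates, while
**compound** tables accept at least one, because a specific active
ingredient may be used on one crop and not the other.  Half-surveyed
double crops carry `unsurveyed = 0.5`; for the aggregate kind their
value is necessarily missing (the unsurveyed component can never have
an estimate), while compound tables use the surveyed component's value
when present.  Unsurveyed crops and non-crop classes are flagged
(`unsurveyed`, `noncrop`) with missing values — conflating "no
estimate" with "zero use" would corrupt landscape means.

Raster reclassification is a pure per-cell lookup producing a value
grid plus a coverage grid (surveyed / unsurveyed / noncrop /
missing-value); the value grid is nodata (−9999) wherever coverage is
not "surveyed", and georeferencing tags (pixel scale, tiepoint, nodata)
pass through bit-exact.  The in-memory value grid is float64 so that
landscape means satisfy the frequency-weighted identity to ~1e-15;
rasters are written as float32, adequate for mapping.  The default
landscape mean averages surveyed cells only; an opt-in mode treats all
non-surveyed cells as zero, a lower bound for whole-landscape loading.
Strict mode rejects raster codes absent from the table; lenient mode
downgrades them to missing-value coverage.

Coverage summaries report the percent of total cells, of cropland
cells, and of cropland excluding pasture/hay carrying (crop-specific)
survey coverage; crop-specific groups are corn, cotton, soybeans,
alfalfa, wheat and rice.  Half-surveyed double-crop cells count
fractionally (0.5).  Percentages are cell-count based, assuming uniform
cell area within a raster — acceptable at the 30 m scales these rasters
use.

## Validation statistics

Relative difference is (a − b)/((a + b)/2) × 100, antisymmetric and
bounded in [−200, 200]; pairs with both estimates zero are undefined
and excluded with counts logged rather than set to 0.  Method 1
reconstructs a reference rate as total kg ÷ harmonized hectares (and
therefore agrees exactly with the pipeline's own rate formula on equal
inputs, a tested invariant); Method 2 multiplies the rate on treated
acres by the treated fraction, applying the acre → hectare constant
exactly once.  Per category the summary reports n, median and quartile
relative difference, a two-sided one-sample Wilcoxon signed-rank test of
median zero (zeros dropped; exact distribution for n ≤ 25, normal
approximation with continuity correction above), Spearman's rho
(average ranks for ties; the classical rank-difference formula for
tie-free data, which returns exactly 1.0 for perfect concordance
instead of 1 − 1 ulp) and Pearson's r (short-circuited to exactly 1.0
for identical columns).  Categories with n < 3 are marked insufficient.
Planted-outlier exclusion lists are applied before computation and
logged.  The treated-fraction trend bins |RD| by percent of area
treated and reports the Spearman correlation of |RD| with percent
treated as a monotone-trend statistic.

## Synthetic data

The generator emulates the structure of the real sources, not their
statistics: state × group × year kg tables with low ≤ high variants and
Bernoulli missingness; census rows only in census years plus annual
survey rows with interior gaps; endpoint exports mixing points, bounds,
regulatory flags and decoys (larval, > 4-day, non-contact/oral route,
non-regulatory points, censored bounds) that the filter and preference
rules must remove; crosswalk keys with valid CASRNs; and a categorical
raster drawn multinomially from a configured class mix including a
double-crop and two non-crop codes, written with 30 m pixel-scale tags.

Two constructions make ground truth exact rather than statistical:
crop-area series are linear in year, so bracketed linear interpolation
of dropped survey years restores them to machine precision; and each
compound's two regulatory points sit log-symmetrically (×1.5, ÷1.5)
around its true LD50, so the geometric-mean consensus recovers the
truth exactly.  Consequently a bundle generated with
`missing_rate_use = 0` yields pipeline rates and loads equal to ground
truth to ≲ 1e-15 relative error, and the end-to-end recovery test
asserts ≤ 1e-9.

Defaults: 3 states, all ten groups, 6 insecticides / 3 fungicides /
3 herbicides, years 1997–2002 (both census years, so every series is
bracketed), 10 % use and area missingness, ln-normal kg draws with
location 9 and spread 1.5 (median ≈ 8 t per state-group-year, heavy
tailed, as pesticide use is), LD50 ranges 0.01–50 µg/bee for
insecticides and 20–200 µg/bee for fungicides/herbicides (insecticides
orders of magnitude more bee-toxic, the others clustering near the
100 µg/bee limit-dose convention), 60 × 60 rasters.  The generator is
fully deterministic under a fixed seed (single integer-state RNG, no
time or locale dependence); identical configs produce byte-identical
bundles.

What the fixtures do **not** emulate: the real spatial autocorrelation
of land cover, realistic state/crop marginal distributions, correlated
missingness, or name messiness requiring fuzzy matching.  Passing tests
therefore demonstrate correctness of the synthesis arithmetic and
conventions, not robustness to the full messiness of the public
sources.

## Problem sizes and budgets

The default test suite and the acceptance script use small
configurations (≤ 5 states, ≤ 20 compounds, 6 years, ≤ 100×100 rasters,
200 random endpoint sets, 100 random series, 50 random rasters) — ample
for exactness checks, and the whole suite runs in seconds.

## Known limitations

- Estimates are state × crop-group × year averages downscaled through
  land cover; they are not field-level measurements, and the package
  deliberately excludes environmental fate, exposure and synergy
  modelling.
- County-level disaggregation, suppressed-value estimation and live
  database querying are out of scope; inputs are file-shaped exports.
- Coverage percentages weight cells, not true areas.
- The Wilcoxon exact/approximate switch at n = 25 is conventional; the
  underlying comparison procedure does not specify one.
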