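# beeload

Pesticide use indicators for pollinator research: compound-level
application rates (kg/ha), aggregate insecticide **bee toxic load**
(honey-bee lethal doses/ha), and the machinery to map both onto
land-cover rasters at field-relevant (30 m) resolution.

## The problem

Public US data on pesticide use, crop area, honey-bee toxicity and land
cover live in four separate databases with incompatible nomenclature,
resolutions and cadences.  Pollinator researchers need those sources
joined into toxicologically meaningful units at landscape scale.
`beeload` implements that synthesis as a tested pipeline:

1. **Crosswalk keys** relate USDA crop names to the ten USGS crop
   groups, compound names to CAS registry numbers, categories and
   mode-of-action (MoA) groups, and crop groups to land-cover class codes.
2. **Crop area**: census acreage (every 5 years) and annual survey
   acreage are harmonized into a complete state × crop group × year
   hectares panel — census wins in census years, survey fills other
   years, and interior gaps are linearly interpolated between the
   nearest surrounding observations.
3. **Toxicity**: heterogeneous acute honey-bee LD50 endpoints are
   filtered to acute (≤ 4 d) adult contact/oral records and resolved to
   one consensus value per compound and route — geometric mean of the
   preferred point-estimate tier (regulatory estimates first), censored
   bounds only when no point exists, and MoA-group / all-insecticide
   median imputation for the remainder.
4. **Rates and load**: for compound *i* with application `kg_i` in a
   state-group-year with area `A` ha,

       rate_i = kg_i / A                      [kg/ha]
       bee toxic load = Σ_i rate_i · 10⁹ / LD50_i   [lethal doses/ha]

   summed over insecticides, on both a contact- and oral-toxicity basis.
5. **Mapping**: state-year load values become land-cover
   reclassification tables (double-crop classes additive; unsurveyed and
   non-crop classes flagged, never zero-filled) which reclassify
   categorical rasters into value + coverage grids with landscape means
   and survey-coverage summaries.
6. **Validation**: relative-difference / rank-correlation /signed-rank
   machinery for comparing the synthesized estimates against an
   independent survey, including the two reference-rate reconstructions
   (total kg ÷ area; rate-on-treated-acres × fraction treated).

A `synthetic_data` generator (`beeload.simulate`) produces
source-shaped fixture bundles with exact ground truth, so the entire
pipeline is testable offline.

## Worked example

```python
import tempfile
from beeload import simulate, pipeline

cfg = simulate.SimConfig(seed=42, n_states=2, missing_rate_use=0.0)
bundle, truth = simulate.generate_fixture_bundle(cfg, tempfile.mkdtemp())
res = pipeline.run(bundle.use, bundle.census, bundle.survey, bundle.ecotox,
                   bundle.ppdb, bundle.crop_key, bundle.compound_key,
                   max_year=None, interpolate=False)
print(res.toxic_load.head(4).to_string(index=False))
```

```
   state usgs_crop_group  year  insecticide_kg_per_ha  lethal_doses_per_ha_contact  lethal_doses_per_ha_oral  interpolated
STATE 01         alfalfa  1997               1.111202                 8.540664e+09              1.312687e+09         False
STATE 01         alfalfa  1998               0.458981                 3.134125e+09              4.498279e+08         False
STATE 01         alfalfa  1999               0.623060                 4.451354e+08              1.284632e+09         False
STATE 01         alfalfa  2000               0.979472                 2.066344e+09              4.973763e+08         False
```

Each row reads: in that state, crop group and year, one hectare received
on average ~1.1 kg of insecticide active ingredients, equivalent to
~8.5 × 10⁹ median lethal doses for a honey bee by contact (the oral
figure differs because contact and oral LD50s differ per compound).
Turning one state-year into a reclass table and applying it to the
bundled land-cover raster:

```python
from beeload import reclass
from beeload.keys import load_key

lc_key = load_key(bundle.landcover_key, "landcover")
sel = res.toxic_load.query("state == 'STATE 01' and year == 1997")
values = dict(zip(sel.usgs_crop_group, sel.lethal_doses_per_ha_oral))
table = reclass.build_reclass_table(values, lc_key, "aggregate")
out = reclass.reclass_raster(reclass.read_geotiff(bundle.raster), table)
print(reclass.landscape_mean(out))
print(reclass.coverage_summary(reclass.read_geotiff(bundle.raster), lc_key))
```

```
3094375002.0494423
{'pct_total_surveyed': 71.30555555555556, 'pct_cropland_surveyed': 93.20987654320987, 'pct_cropland_crop_specific': 93.20987654320987}
```

i.e. the surveyed portion of this landscape carries ~3.1 × 10⁹ oral
lethal doses/ha on average, 71 % of all cells (93 % of cropland) are
covered by the underlying use survey, and all of that cropland carries a
crop-specific estimate.  The wheat/soybean double-crop class received
the *sum* of the wheat and soybean values; oats (unsurveyed) and the two
non-crop classes are flagged and excluded from the mean rather than
counted as zero.

The same steps are scriptable via the `beeload` CLI
(`simulate`, `build-ld50`, `build-area`, `build-rates`, `build-toxload`,
`make-reclass`, `reclass-raster`, `coverage`, `validate`).

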