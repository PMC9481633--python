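"""Reclassification tables, raster reclassification, means, coverage."""

import numpy as np
import pandas as pd
import pytest

from beeload import reclass
from beeload.keys import LandCoverKey

CORN = LandCoverKey(1, "Corn", "single_crop", ("corn",), 1)
SOY = LandCoverKey(5, "Soybeans", "single_crop", ("soybeans",), 1)
WHEAT = LandCoverKey(24, "Winter Wheat", "single_crop", ("wheat",), 1)
DBL = LandCoverKey(26, "Dbl WinWht/Soy", "double_crop", ("wheat", "soybeans"), 2)
DBL_HALF = LandCoverKey(225, "Dbl Oats/Corn", "double_crop", ("corn", "other_crops"), 1)
OATS = LandCoverKey(28, "Oats", "single_crop", ("other_crops",), 0)
FOREST = LandCoverKey(141, "Forest", "noncrop", (), 0)
ALL = [CORN, SOY, WHEAT, DBL, DBL_HALF, OATS, FOREST]


class TestBuildReclassTable:
    @pytest.mark.parametrize("kind", ["aggregate", "compound"])
    def test_double_crop_is_additive(self, kind):
        table = reclass.build_reclass_table(
            {"wheat": 1.0, "soybeans": 2.0}, [WHEAT, SOY, DBL], kind
        ).set_index("cdl_code")
        assert table.loc[26, "value"] == 3.0
        assert table.loc[26, "value"] == table.loc[24, "value"] + table.loc[5, "value"]

    def test_aggregate_requires_both_components(self):
        table = reclass.build_reclass_table({"wheat": 1.0}, [DBL], "aggregate")
        assert np.isnan(table.loc[0, "value"])

    def test_compound_accepts_one_component(self):
        table = reclass.build_reclass_table({"wheat": 1.0}, [DBL], "compound")
        assert table.loc[0, "value"] == 1.0

    def test_half_surveyed_double_crop_flagged(self):
        table = reclass.build_reclass_table({"corn": 2.0}, [DBL_HALF], "compound")
        assert table.loc[0, "unsurveyed"] == 0.5
        assert table.loc[0, "value"] == 2.0

    def test_half_surveyed_double_crop_aggregate_missing(self):
        table = reclass.build_reclass_table({"corn": 2.0}, [DBL_HALF], "aggregate")
        assert table.loc[0, "unsurveyed"] == 0.5
        assert np.isnan(table.loc[0, "value"])

    def test_noncrop_and_unsurveyed_flags(self):
        table = reclass.build_reclass_table({"corn": 2.0}, ALL, "aggregate")
        t = table.set_index("cdl_code")
        assert t.loc[141, "noncrop"] == 1 and np.isnan(t.loc[141, "value"])
        assert t.loc[141, "unsurveyed"] == 0
        assert t.loc[28, "unsurveyed"] == 1 and np.isnan(t.loc[28, "value"])


def make_load_raster(grid, values, kind="aggregate", key=ALL):
    raster = reclass.Raster(np.asarray(grid, dtype=np.uint16))
    table = reclass.build_reclass_table(values, key, kind)
    return reclass.reclass_raster(raster, table)


class TestReclassRaster:
    def test_per_cell_lookup(self):
        out = make_load_raster([[1, 1], [5, 5]], {"corn": 2.0, "soybeans": 4.0},
                               key=[CORN, SOY])
        np.testing.assert_array_equal(out.values.data, [[2.0, 2.0], [4.0, 4.0]])
        assert (out.coverage == reclass.COVERAGE_SURVEYED).all()

    def test_noncrop_cells_become_nodata(self):
        out = make_load_raster([[1, 141]], {"corn": 2.0})
        assert out.values.data[0, 1] == reclass.DEFAULT_NODATA
        assert out.coverage[0, 1] == reclass.COVERAGE_NONCROP

    def test_missing_value_coverage(self):
        out = make_load_raster([[1, 24]], {"corn": 2.0})  # no wheat estimate
        assert out.coverage[0, 1] == reclass.COVERAGE_MISSING_VALUE
        assert out.values.data[0, 1] == reclass.DEFAULT_NODATA

    def test_strict_mode_rejects_unknown_codes(self):
        raster = reclass.Raster(np.array([[1, 99]], dtype=np.uint16))
        table = reclass.build_reclass_table({"corn": 2.0}, [CORN], "aggregate")
        with pytest.raises(reclass.ReclassError, match="99"):
            reclass.reclass_raster(raster, table)
        lenient = reclass.reclass_raster(raster, table, strict=False)
        assert lenient.coverage[0, 1] == reclass.COVERAGE_MISSING_VALUE

    def test_cell_tallies_match_generator_truth(self, clean_bundle):
        bundle, truth = clean_bundle
        raster = reclass.read_geotiff(bundle.raster)
        codes, counts = np.unique(raster.data, return_counts=True)
        assert {int(c): int(n) for c, n in zip(codes, counts)} == truth.true_class_counts

    def test_reclassification_is_pure_per_cell(self):
        rng = np.random.default_rng(3)
        grid = rng.choice([1, 5, 141], size=(8, 8))
        values = {"corn": 1.5, "soybeans": 2.5}
        out = make_load_raster(grid, values, key=[CORN, SOY, FOREST])
        perm = rng.permutation(64)
        out_perm = make_load_raster(grid.ravel()[perm].reshape(8, 8), values,
                                    key=[CORN, SOY, FOREST])
        np.testing.assert_array_equal(
            out.values.data.ravel()[perm], out_perm.values.data.ravel()
        )


class TestGeoTiffRoundTrip:
    def test_georeferencing_preserved_bit_exact(self, tmp_path):
        raster = reclass.Raster(
            np.arange(12, dtype=np.uint16).reshape(3, 4),
            pixel_scale=(30.0, 30.0, 0.0),
            tiepoint=(0, 0, 0, 123456.75, 654321.5, 0.0),
            nodata=-9999.0,
        )
        path = tmp_path / "r.tif"
        reclass.write_geotiff(raster, path)
        back = reclass.read_geotiff(path)
        np.testing.assert_array_equal(back.data, raster.data)
        assert back.pixel_scale == raster.pixel_scale
        assert back.tiepoint == raster.tiepoint
        assert back.nodata == raster.nodata


class TestLandscapeMean:
    def test_mean_over_surveyed_cells(self):
        out = make_load_raster([[1, 1], [5, 5]], {"corn": 2.0, "soybeans": 4.0},
                               key=[CORN, SOY])
        assert reclass.landscape_mean(out) == 3.0

    def test_noncrop_half_raster(self):
        out = make_load_raster([[1, 141]], {"corn": 2.0})
        assert reclass.landscape_mean(out) == 2.0
        assert reclass.landscape_mean(out, include_nonsurveyed_as_zero=True) == 1.0

    def test_surveyed_mean_invariant_to_added_noncrop(self):
        base = make_load_raster([[1, 5]], {"corn": 2.0, "soybeans": 4.0})
        padded = make_load_raster([[1, 5], [141, 141]], {"corn": 2.0, "soybeans": 4.0})
        assert reclass.landscape_mean(base) == reclass.landscape_mean(padded)

    def test_no_surveyed_cells_is_error(self):
        out = make_load_raster([[141]], {})
        with pytest.raises(reclass.ReclassError):
            reclass.landscape_mean(out)

    def test_mean_equals_frequency_weighted_table(self):
        rng = np.random.default_rng(11)
        grid = rng.choice([1, 5, 24, 141], size=(40, 40), p=[0.4, 0.3, 0.2, 0.1])
        values = {"corn": 0.8, "soybeans": 1.6, "wheat": 2.4}
        out = make_load_raster(grid, values, key=[CORN, SOY, WHEAT, FOREST])
        codes, counts = np.unique(grid, return_counts=True)
        freq = dict(zip(codes.tolist(), counts.tolist()))
        code_value = {1: 0.8, 5: 1.6, 24: 2.4}
        surveyed = sum(freq.get(c, 0) for c in code_value)
        expected = sum(freq.get(c, 0) * v for c, v in code_value.items()) / surveyed
        assert reclass.landscape_mean(out) == pytest.approx(expected, abs=1e-12)


class TestCoverageSummary:
    def test_all_corn(self):
        summary = reclass.coverage_summary(np.full((4, 4), 1, dtype=np.uint16), ALL)
        assert summary == {"pct_total_surveyed": 100.0,
                           "pct_cropland_surveyed": 100.0,
                           "pct_cropland_crop_specific": 100.0}

    def test_half_forest_half_corn(self):
        grid = np.array([[1, 141], [1, 141]], dtype=np.uint16)
        summary = reclass.coverage_summary(grid, ALL)
        assert summary["pct_total_surveyed"] == 50.0
        assert summary["pct_cropland_surveyed"] == 100.0
        assert summary["pct_cropland_crop_specific"] == 100.0

    def test_mixed_composition_hand_computed(self):
        # 4 corn, 2 oats (unsurveyed crop), 2 forest, 2 half-surveyed double crop
        grid = np.array([1, 1, 1, 1, 28, 28, 141, 141, 225, 225], dtype=np.uint16)
        summary = reclass.coverage_summary(grid.reshape(2, 5), ALL)
        # surveyed weight: 4*1 + 2*0 + 2*(1/2) = 5 of 10 total, 8 cropland
        assert summary["pct_total_surveyed"] == pytest.approx(50.0)
        assert summary["pct_cropland_surveyed"] == pytest.approx(100 * 5 / 8)
        # crop-specific: corn cells 4 + double 2*(1/2 corn) = 5 of 8 (no pasture here)
        assert summary["pct_cropland_crop_specific"] == pytest.approx(100 * 5 / 8)

    def test_pasture_excluded_from_crop_specific_denominator(self):
        pasture = LandCoverKey(37, "Other Hay", "single_crop", ("pasture_hay",), 1)
        grid = np.array([[1, 37]], dtype=np.uint16)
        summary = reclass.coverage_summary(grid, [CORN, pasture])
        assert summary["pct_cropland_surveyed"] == 100.0
        assert summary["pct_cropland_crop_specific"] == 100.0  # pasture not in denom
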