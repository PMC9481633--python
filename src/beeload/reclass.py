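"""Land-cover reclassification: tables, rasters, landscape means, coverage.

A reclassification table maps each land-cover class code of a categorical
raster (CDL-style, 30 m nominal) to the predicted pesticide value of its
crop group(s) for one state and year.  Double-crop classes (two crops
grown sequentially in one year) are treated additively; for the aggregate
insecticide table a double-crop value is reported only when both
components have estimates, while compound-specific tables accept at least
one.  Non-crop classes and unsurveyed crops are flagged (``noncrop``,
``unsurveyed``; 0.5 marks a double crop with one unsurveyed component)
rather than zero-filled, because "no estimate" and "zero use" must not be
conflated when averaging over a landscape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from beeload.keys import LandCoverKey

#: Crop groups with a crop-specific (single-crop) use estimate.
CROP_SPECIFIC_GROUPS = frozenset(
    {"corn", "cotton", "soybeans", "alfalfa", "wheat", "rice"}
)

COVERAGE_SURVEYED = 0
COVERAGE_UNSURVEYED = 1
COVERAGE_NONCROP = 2
COVERAGE_MISSING_VALUE = 3

DEFAULT_NODATA = -9999.0

# GeoTIFF / GDAL tag codes used to carry georeferencing through reclassification
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class ReclassError(ValueError):
    pass


@dataclass
class Raster:
    """A single-band raster with GeoTIFF-style georeferencing metadata.

    ``pixel_scale`` is (sx, sy, sz) in map units per pixel and ``tiepoint``
    the (i, j, k, x, y, z) raster-to-model tie, both passed through I/O
    unchanged so reclassified outputs stay aligned with their input.
    """

    data: np.ndarray
    pixel_scale: tuple[float, float, float] = (30.0, 30.0, 0.0)
    tiepoint: tuple[float, float, float, float, float, float] = (0, 0, 0, 0.0, 0.0, 0.0)
    nodata: float | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def write_geotiff(raster: Raster, path: str | Path) -> None:
    """Write a raster as a tagged TIFF with pixel-scale/tiepoint/nodata tags."""
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, tuple(float(v) for v in raster.pixel_scale)),
        (_TAG_MODEL_TIEPOINT, "d", 6, tuple(float(v) for v in raster.tiepoint)),
    ]
    if raster.nodata is not None:
        nod = repr(raster.nodata).encode() + b"\x00"
        extratags.append((_TAG_GDAL_NODATA, "s", len(nod), nod))
    tifffile.imwrite(path, raster.data, extratags=extratags)


def read_geotiff(path: str | Path) -> Raster:
    """Read a single-band tagged TIFF back into a :class:`Raster`."""
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray()
        tags = page.tags
        scale = tags.get(_TAG_MODEL_PIXEL_SCALE)
        tie = tags.get(_TAG_MODEL_TIEPOINT)
        nod = tags.get(_TAG_GDAL_NODATA)
        pixel_scale = tuple(scale.value) if scale else (1.0, 1.0, 0.0)
        tiepoint = tuple(tie.value) if tie else (0, 0, 0, 0.0, 0.0, 0.0)
        nodata = float(str(nod.value).strip("\x00")) if nod else None
    return Raster(data=data, pixel_scale=pixel_scale, tiepoint=tiepoint, nodata=nodata)


@dataclass
class LoadRaster:
    """Reclassified value raster plus a per-cell coverage-code companion.

    Coverage codes: 0 surveyed, 1 unsurveyed, 2 noncrop, 3 missing value.
    The value grid is nodata wherever coverage != surveyed.
    """

    values: Raster
    coverage: np.ndarray

    def surveyed_mask(self) -> np.ndarray:
        return self.coverage == COVERAGE_SURVEYED


def build_reclass_table(
    values: Mapping[str, float],
    key: Sequence[LandCoverKey],
    table_kind: str,
    state: str | None = None,
    year: int | None = None,
) -> pd.DataFrame:
    """Build one state-year reclassification table from group values.

    Parameters
    ----------
    values:
        Partial map crop group -> predicted value (kg/ha or doses/ha).
    key:
        Land-cover key rows; one output row per code.
    table_kind:
        ``"aggregate"``: a double-crop value requires estimates for both
        components; ``"compound"``: the sum of whichever components have
        estimates (a compound may be used on one crop but not the other).

    Rules per code: single surveyed crop takes its group's value (missing
    if the group has no estimate); unsurveyed crop -> ``unsurveyed=1``,
    value missing; noncrop -> ``noncrop=1``, value missing; double crops
    sum components additively per the table kind, with ``unsurveyed=0.5``
    when exactly one component is surveyed.
    """
    if table_kind not in {"aggregate", "compound"}:
        raise ValueError(f"table_kind must be 'aggregate' or 'compound', got {table_kind!r}")
    clean = {g: v for g, v in values.items() if v is not None and not pd.isna(v)}
    rows = []
    for lc in key:
        value: float | None = None
        unsurveyed = 0.0
        noncrop = 0.0
        if lc.kind == "noncrop":
            noncrop = 1.0
        elif lc.kind == "single_crop":
            if lc.surveyed_components == 0:
                unsurveyed = 1.0
            else:
                value = clean.get(lc.component_groups[0])
        else:  # double_crop; surveyed components listed first in the key
            surveyed = lc.component_groups[: lc.surveyed_components]
            if lc.surveyed_components == 0:
                unsurveyed = 1.0
            elif lc.surveyed_components == 1:
                unsurveyed = 0.5
            available = [clean[g] for g in surveyed if g in clean]
            if lc.surveyed_components == 2:
                if table_kind == "aggregate":
                    value = sum(available) if len(available) == 2 else None
                else:
                    value = sum(available) if available else None
            elif lc.surveyed_components == 1 and table_kind == "compound" and available:
                # aggregate kind needs both crops estimated, impossible here
                value = available[0]
        rows.append(
            {
                "state": state,
                "year": year,
                "cdl_code": lc.cdl_code,
                "cdl_name": lc.cdl_name,
                "value": np.nan if value is None else float(value),
                "unsurveyed": unsurveyed,
                "noncrop": noncrop,
            }
        )
    return pd.DataFrame(rows)


def reclass_raster(
    landcover: Raster, table: pd.DataFrame, strict: bool = True
) -> LoadRaster:
    """Reclassify a categorical raster through a reclass table, per cell.

    Produces a float32 value raster (nodata outside surveyed estimates) and
    a coverage raster distinguishing surveyed, unsurveyed, noncrop and
    missing-value cells.  Codes absent from the table raise in strict mode;
    otherwise they downgrade to missing-value coverage.
    """
    codes = np.unique(landcover.data)
    known = set(table["cdl_code"].astype(int))
    unknown = sorted(int(c) for c in codes if int(c) not in known)
    if unknown and strict:
        raise ReclassError(f"raster codes missing from reclass table: {unknown}")

    max_code = int(codes.max()) if codes.size else 0
    value_lut = np.full(max_code + 1, np.nan, dtype=np.float64)
    coverage_lut = np.full(max_code + 1, COVERAGE_MISSING_VALUE, dtype=np.uint8)
    for _, row in table.iterrows():
        code = int(row["cdl_code"])
        if code > max_code:
            continue
        if row["noncrop"] == 1:
            coverage_lut[code] = COVERAGE_NONCROP
        elif row["unsurveyed"] == 1:
            coverage_lut[code] = COVERAGE_UNSURVEYED
        elif pd.isna(row["value"]):
            coverage_lut[code] = COVERAGE_MISSING_VALUE
        else:
            coverage_lut[code] = COVERAGE_SURVEYED
            value_lut[code] = float(row["value"])

    idx = landcover.data.astype(np.intp)
    coverage = coverage_lut[idx]
    # float64 in memory so landscape means stay exact; cast on file output
    values = value_lut[idx]
    values[coverage != COVERAGE_SURVEYED] = DEFAULT_NODATA
    return LoadRaster(
        values=Raster(
            data=values,
            pixel_scale=landcover.pixel_scale,
            tiepoint=landcover.tiepoint,
            nodata=DEFAULT_NODATA,
        ),
        coverage=coverage,
    )


def landscape_mean(raster: LoadRaster, include_nonsurveyed_as_zero: bool = False) -> float:
    """Mean predicted value over a reclassified landscape.

    Default: mean over surveyed cells only.  The opt-in zero-fill mode
    averages over every cell, treating non-surveyed cells as zero use —
    a lower bound useful for whole-landscape loading comparisons.
    """
    mask = raster.surveyed_mask()
    n_surveyed = int(mask.sum())
    if include_nonsurveyed_as_zero:
        if raster.coverage.size == 0:
            raise ReclassError("empty raster")
        total = float(raster.values.data[mask].astype(np.float64).sum())
        return total / raster.coverage.size
    if n_surveyed == 0:
        raise ReclassError("no surveyed cells; cannot form a surveyed-only mean")
    return float(raster.values.data[mask].astype(np.float64).mean())


def coverage_summary(
    landcover: Raster | np.ndarray, key: Sequence[LandCoverKey]
) -> dict[str, float]:
    """Survey-coverage percentages of a land-cover raster.

    Returns ``pct_total_surveyed`` (share of all cells covered by the use
    survey), ``pct_cropland_surveyed`` (same share within cropland), and
    ``pct_cropland_crop_specific`` (share of cropland, excluding
    pasture/hay, carrying a crop-specific rather than grouped estimate:
    corn, cotton, soybeans, alfalfa, wheat, rice).  Partially surveyed
    double-crop cells count fractionally.  Percentages are cell-count
    based (uniform cell area within a raster).
    """
    data = landcover.data if isinstance(landcover, Raster) else landcover
    codes, counts = np.unique(data, return_counts=True)
    by_code = {lc.cdl_code: lc for lc in key}
    missing = sorted(int(c) for c in codes if int(c) not in by_code)
    if missing:
        raise ReclassError(f"raster codes missing from land-cover key: {missing}")

    total = float(data.size)
    surveyed_w = 0.0
    crop_cells = 0.0
    crop_specific_w = 0.0
    crop_specific_denom = 0.0
    for code, count in zip(codes, counts):
        lc = by_code[int(code)]
        n = float(count)
        if lc.kind == "noncrop":
            continue
        ncomp = len(lc.component_groups)
        surveyed_w += n * lc.surveyed_components / ncomp
        crop_cells += n
        if set(lc.component_groups) == {"pasture_hay"}:
            continue
        crop_specific_denom += n
        specific = sum(
            1
            for g in lc.component_groups[: lc.surveyed_components]
            if g in CROP_SPECIFIC_GROUPS
        )
        crop_specific_w += n * specific / ncomp
    return {
        "pct_total_surveyed": 100.0 * surveyed_w / total if total else 0.0,
        "pct_cropland_surveyed": 100.0 * surveyed_w / crop_cells if crop_cells else 0.0,
        "pct_cropland_crop_specific": (
            100.0 * crop_specific_w / crop_specific_denom if crop_specific_denom else 0.0
        ),
    }
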