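"""Harmonize census and annual-survey acreage into a complete hectares panel.

The agricultural census is comprehensive but quinquennial (1997, 2002,
2007, 2012, 2017); the annual survey covers fewer crops but fills the
years between.  The panel is assembled per state and crop by taking the
census value in census years, the survey value otherwise, and linear
interpolation between the nearest surrounding observations for interior
gaps.  Hectares are then summed by USGS crop group, with California
processed against its own crop key because its pesticide source data
cover a different crop list.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from beeload.keys import CropKey, normalize_name

CENSUS_YEARS = (1997, 2002, 2007, 2012, 2017)

#: International acre in hectares.
HA_PER_ACRE = 0.40468564224

YEAR_MIN, YEAR_MAX = 1997, 2017

AREA_COLUMNS = ["state", "crop", "year", "area", "unit", "source"]


class AreaError(ValueError):
    pass


def read_quickstats(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a Quick-Stats-shaped CSV into (census, survey) acre tables.

    Expected columns: program (CENSUS or SURVEY), state, commodity, year,
    value (acres).  Names are normalized for joining.
    """
    df = pd.read_csv(path)
    df["program"] = df["program"].str.strip().str.upper()
    out = pd.DataFrame(
        {
            "state": df["state"].map(normalize_name),
            "crop": df["commodity"].map(normalize_name),
            "year": df["year"].astype(int),
            "area": df["value"].astype(float),
            "unit": "acres",
        }
    )
    census = out[df["program"].values == "CENSUS"].copy()
    survey = out[df["program"].values == "SURVEY"].copy()
    census["source"] = "census"
    survey["source"] = "survey"
    return census.reset_index(drop=True), survey.reset_index(drop=True)


def _check_no_duplicates(df: pd.DataFrame, label: str) -> None:
    dup = df.duplicated(subset=["state", "crop", "year"], keep=False)
    if dup.any():
        offending = df.loc[dup, ["state", "crop", "year"]].drop_duplicates()
        raise AreaError(
            f"conflicting duplicate rows in {label} source:\n{offending.to_string(index=False)}"
        )


def select_area_source(census: pd.DataFrame, survey: pd.DataFrame) -> pd.DataFrame:
    """Collapse census and survey records to one row per (state, crop, year).

    Census wins in census years even when a survey value coexists; survey
    supplies the remaining years.  Inputs must already be state-level,
    contiguous-US, year >= 1997.
    """
    _check_no_duplicates(census, "census")
    _check_no_duplicates(survey, "survey")
    bad = census[~census["year"].isin(CENSUS_YEARS)]
    if not bad.empty:
        raise AreaError(f"census records outside census years: {sorted(bad['year'].unique())}")
    merged = pd.concat([census, survey], ignore_index=True)
    # census sorts before survey; keep='first' enforces census precedence
    merged["_rank"] = (merged["source"] != "census").astype(int)
    merged = merged.sort_values(["state", "crop", "year", "_rank"], kind="stable")
    merged = merged.drop_duplicates(subset=["state", "crop", "year"], keep="first")
    return merged.drop(columns="_rank").reset_index(drop=True)[AREA_COLUMNS]


def interpolate_series(series: Mapping[int, float]) -> dict[int, tuple[float, str]]:
    """Fill interior gaps of a year -> area series by bracketed linear interpolation.

    Every missing year strictly between two observed years is filled from
    the nearest bracketing observations; years outside the observed span are
    left unfilled (no extrapolation).  Returns year -> (area, source) with
    source ``"observed"`` or ``"interpolated"``.
    """
    if not series:
        return {}
    years = sorted(series)
    out: dict[int, tuple[float, str]] = {y: (float(series[y]), "observed") for y in years}
    for lo, hi in zip(years, years[1:]):
        v0, v1 = series[lo], series[hi]
        for y in range(lo + 1, hi):
            out[y] = (v0 + (y - lo) * (v1 - v0) / (hi - lo), "interpolated")
    return dict(sorted(out.items()))


def interpolate_panel(records: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`interpolate_series` to every (state, crop) series."""
    pieces = []
    for (state, crop), grp in records.groupby(["state", "crop"], sort=True):
        unit = grp["unit"].iloc[0]
        source_by_year = dict(zip(grp["year"], grp["source"]))
        filled = interpolate_series(dict(zip(grp["year"], grp["area"])))
        for year, (value, src) in filled.items():
            pieces.append(
                {
                    "state": state,
                    "crop": crop,
                    "year": year,
                    "area": value,
                    "unit": unit,
                    "source": source_by_year.get(year, "interpolated")
                    if src == "observed"
                    else "interpolated",
                }
            )
    return pd.DataFrame(pieces, columns=AREA_COLUMNS)


def to_hectares(records: pd.DataFrame) -> pd.DataFrame:
    """Convert acre records to hectares (international acre, 0.40468564224 ha).

    Raises on records already in hectares to guard against double
    conversion.
    """
    if (records["unit"] == "hectares").any():
        raise AreaError("records already in hectares; refusing double conversion")
    unknown = set(records["unit"].unique()) - {"acres"}
    if unknown:
        raise AreaError(f"unknown area units: {sorted(unknown)}")
    out = records.copy()
    out["area"] = out["area"] * HA_PER_ACRE
    out["unit"] = "hectares"
    return out


def aggregate_groups(
    records: pd.DataFrame,
    key: Sequence[CropKey],
    california_key: Sequence[CropKey] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Sum hectares by (state, usgs_crop_group, year).

    California rows join against ``california_key`` when given (its source
    pesticide data cover a different crop list); all other rows use the
    national key.  Returns the group panel plus the sorted list of crop
    names found in no key (excluded, never silently).

    The group panel carries ``interpolated_fraction``: the share of each
    group-state-year's hectares contributed by interpolated records.
    """
    if (records["unit"] != "hectares").any():
        raise AreaError("aggregate_groups requires hectares")
    national = {k.usda_crop_name: k.usgs_crop_group for k in key if k.usgs_crop_group}
    california = (
        {k.usda_crop_name: k.usgs_crop_group for k in california_key if k.usgs_crop_group}
        if california_key is not None
        else national
    )

    is_ca = records["state"] == "CALIFORNIA"
    group = np.where(
        is_ca,
        records["crop"].map(california),
        records["crop"].map(national),
    )
    df = records.assign(usgs_crop_group=group)
    unmatched = sorted(df.loc[df["usgs_crop_group"].isna(), "crop"].unique())
    df = df.dropna(subset=["usgs_crop_group"])

    df = df.assign(
        interp_ha=np.where(df["source"] == "interpolated", df["area"], 0.0)
    )
    agg = (
        df.groupby(["state", "usgs_crop_group", "year"], sort=True)
        .agg(hectares=("area", "sum"), interp_ha=("interp_ha", "sum"))
        .reset_index()
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(agg["hectares"] > 0, agg["interp_ha"] / agg["hectares"], 0.0)
    agg["interpolated_fraction"] = frac
    return agg.drop(columns="interp_ha"), unmatched


def build_area_panel(
    census: pd.DataFrame,
    survey: pd.DataFrame,
    key: Sequence[CropKey],
    california_key: Sequence[CropKey] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Full acreage pipeline: source selection, interpolation, conversion, grouping."""
    selected = select_area_source(census, survey)
    filled = interpolate_panel(selected)
    hectares = to_hectares(filled)
    return aggregate_groups(hectares, key, california_key)
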