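"""Application rates (kg/ha) and aggregate bee toxic load (lethal doses/ha).

Average application rates divide kg of active ingredient applied by the
crop-group area (ha) per compound, state, crop group, and year.  The
aggregate insecticide indicator, bee toxic load, converts each
insecticide's rate into honey-bee lethal doses per hectare by dividing by
its consensus LD50 (ug/bee; kg -> ug bridge of 1e9) and sums across
insecticides, on both a contact- and an oral-toxicity basis.  Aggregate
series end at 2014 by default because seed-applied pesticides — a major
contributor to bee toxic load — are excluded from the source data after
that year.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from beeload.keys import CompoundKey

UG_PER_KG = 1e9

#: Last year with seed-treatment data in the use source.
AGGREGATE_END_YEAR = 2014

LOAD_MEASURES = (
    "insecticide_kg_per_ha",
    "lethal_doses_per_ha_contact",
    "lethal_doses_per_ha_oral",
)


class RateError(ValueError):
    pass


def compute_rates(
    use: pd.DataFrame, area: pd.DataFrame, variant: str = "low"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join use (kg) to area (ha) and form kg/ha rates.

    Parameters
    ----------
    use:
        Columns compound, state, usgs_crop_group, year, kg_low, kg_high.
    area:
        Group panel with columns state, usgs_crop_group, year, hectares.
    variant:
        ``"low"`` (default, matching the source's better-validated estimate)
        or ``"high"``.

    Returns
    -------
    (rates, flagged):
        ``rates`` has one row per use row with a positive matching area;
        ``flagged`` collects use rows with missing or zero area (undefined
        rate) so nothing is dropped silently.
    """
    if variant not in {"low", "high"}:
        raise ValueError(f"variant must be 'low' or 'high', got {variant!r}")
    kg_col = f"kg_{variant}"
    if (use[kg_col].dropna() < 0).any():
        raise RateError("negative kg applied")
    df = use.merge(
        area[["state", "usgs_crop_group", "year", "hectares"]],
        on=["state", "usgs_crop_group", "year"],
        how="left",
    )
    df = df.dropna(subset=[kg_col])  # missing use is "no data", not zero
    undefined = df["hectares"].isna() | (df["hectares"] <= 0)
    flagged = df.loc[undefined].copy()
    flagged["reason"] = np.where(
        flagged["hectares"].isna(), "no_matching_area", "zero_area"
    )
    ok = df.loc[~undefined].copy()
    ok["kg_per_ha"] = ok[kg_col] / ok["hectares"]
    ok["estimate_variant"] = variant
    rates = ok[
        ["compound", "state", "usgs_crop_group", "year", "kg_per_ha", "estimate_variant"]
    ].reset_index(drop=True)
    return rates, flagged.reset_index(drop=True)


def lethal_doses_per_ha(rate_kg_per_ha, ld50_ug_per_bee):
    """Honey-bee lethal doses per hectare: rate (kg/ha) x 1e9 / LD50 (ug/bee)."""
    ld50 = np.asarray(ld50_ug_per_bee, dtype=float)
    if np.any(ld50 <= 0):
        raise RateError("LD50 must be positive")
    result = np.asarray(rate_kg_per_ha, dtype=float) * UG_PER_KG / ld50
    return float(result) if result.ndim == 0 else result


def compute_toxic_load(
    rates: pd.DataFrame,
    ld50_table: pd.DataFrame,
    compound_key: Sequence[CompoundKey],
    max_year: int | None = AGGREGATE_END_YEAR,
) -> pd.DataFrame:
    """Aggregate insecticide rates into bee toxic load per state-group-year.

    Filters ``rates`` to insecticides (via the compound key), joins the
    consensus LD50 table, and sums kg/ha and contact/oral lethal doses/ha
    across compounds.  ``max_year=None`` disables the default truncation
    at 2014.

    Raises if an insecticide in ``rates`` is missing from ``ld50_table`` —
    the consensus table is complete by construction, so a gap indicates a
    pipeline-ordering defect upstream.
    """
    insecticides = {ck.usgs_name for ck in compound_key if ck.category == "insecticide"}
    df = rates[rates["compound"].isin(insecticides)].copy()
    if max_year is not None:
        df = df[df["year"] <= max_year]
    if df.empty:
        return pd.DataFrame(
            columns=["state", "usgs_crop_group", "year", *LOAD_MEASURES, "interpolated"]
        )
    missing = set(df["compound"]) - set(ld50_table["compound"])
    if missing:
        raise RateError(
            f"insecticide(s) missing from LD50 table: {sorted(missing)}; "
            "run the consensus/imputation step first"
        )
    df = df.merge(
        ld50_table[["compound", "ld50_contact_ug_bee", "ld50_oral_ug_bee"]],
        on="compound",
        how="left",
    )
    df["doses_contact"] = lethal_doses_per_ha(df["kg_per_ha"], df["ld50_contact_ug_bee"])
    df["doses_oral"] = lethal_doses_per_ha(df["kg_per_ha"], df["ld50_oral_ug_bee"])
    out = (
        df.groupby(["state", "usgs_crop_group", "year"], sort=True)
        .agg(
            insecticide_kg_per_ha=("kg_per_ha", "sum"),
            lethal_doses_per_ha_contact=("doses_contact", "sum"),
            lethal_doses_per_ha_oral=("doses_oral", "sum"),
        )
        .reset_index()
    )
    out["interpolated"] = False
    return out


def interpolate_loads(panel: pd.DataFrame) -> pd.DataFrame:
    """Fill interior year gaps of each (state, group) load series linearly.

    Each measure is interpolated independently between its nearest
    bracketing observed years; gaps before the first or after the last
    observation remain missing.  Filled rows carry ``interpolated=True``.
    """
    from beeload.area import interpolate_series

    pieces = []
    for (state, group), grp in panel.groupby(["state", "usgs_crop_group"], sort=True):
        observed_years = set(grp["year"])
        filled: dict[int, dict] = {}
        for measure in LOAD_MEASURES:
            series = dict(zip(grp["year"], grp[measure]))
            series = {y: v for y, v in series.items() if pd.notna(v)}
            for year, (value, _src) in interpolate_series(series).items():
                filled.setdefault(year, {})[measure] = value
        for year in sorted(filled):
            pieces.append(
                {
                    "state": state,
                    "usgs_crop_group": group,
                    "year": year,
                    **{m: filled[year].get(m, np.nan) for m in LOAD_MEASURES},
                    "interpolated": year not in observed_years,
                }
            )
    return pd.DataFrame(
        pieces, columns=["state", "usgs_crop_group", "year", *LOAD_MEASURES, "interpolated"]
    )
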