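"""End-to-end driver: source files in, rates / loads / reclass tables out."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from beeload import area, rates, toxicity
from beeload.keys import load_key


@dataclass
class PipelineResult:
    area_panel: pd.DataFrame
    unmatched_crops: list[str]
    ld50_table: pd.DataFrame
    rates: pd.DataFrame
    flagged_use: pd.DataFrame
    toxic_load: pd.DataFrame


def run(
    use_path: str | Path,
    census_path: str | Path,
    survey_path: str | Path,
    ecotox_path: str | Path,
    ppdb_path: str | Path,
    crop_key_path: str | Path,
    compound_key_path: str | Path,
    ca_crop_key_path: str | Path | None = None,
    variant: str = "low",
    max_year: int | None = rates.AGGREGATE_END_YEAR,
    interpolate: bool = True,
) -> PipelineResult:
    """Run the full synthesis on source-shaped CSV inputs.

    The use file supplies kg per compound-state-group-year (low and high
    variants); census/survey files are Quick-Stats-shaped acreage; the two
    toxicity files are database-export-shaped endpoint tables.  Returns
    every intermediate product a user would write out.
    """
    crop_key = load_key(crop_key_path, "crop")
    ca_key = load_key(ca_crop_key_path, "crop") if ca_crop_key_path else None
    compound_key = load_key(compound_key_path, "compound")

    census_a, survey_a = area.read_quickstats(census_path)
    census_b, survey_b = area.read_quickstats(survey_path)
    census = pd.concat([census_a, census_b], ignore_index=True)
    survey = pd.concat([survey_a, survey_b], ignore_index=True)
    panel, unmatched = area.build_area_panel(census, survey, crop_key, ca_key)

    ld50 = toxicity.build_ld50_table(ecotox_path, ppdb_path, compound_key)

    use = pd.read_csv(use_path)
    rate_table, flagged = rates.compute_rates(use, panel, variant=variant)
    loads = rates.compute_toxic_load(rate_table, ld50, compound_key, max_year=max_year)
    if interpolate and not loads.empty:
        loads = rates.interpolate_loads(loads)
    return PipelineResult(
        area_panel=panel,
        unmatched_crops=unmatched,
        ld50_table=ld50,
        rates=rate_table,
        flagged_use=flagged,
        toxic_load=loads,
    )
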