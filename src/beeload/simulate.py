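"""Synthetic fixtures with exact ground truth for the whole pipeline.

Generates the full bundle of source-shaped files — use survey kg tables
(low/high variants with structured missingness), census + annual-survey
acreage with gaps, toxicity endpoint exports with decoy records that the
acute/adult filter must remove, crosswalk keys, and a categorical
land-cover raster — together with the exact rates, loads, LD50s and class
counts they encode, so every downstream module is testable without
external downloads.

Design choices that make ground truth exact rather than approximate:
crop-area series are linear in year, so bracketed linear interpolation
of survey gaps restores them to machine precision; each compound's two
regulatory point endpoints are placed log-symmetrically around its true
LD50, so the geometric-mean consensus recovers it.  kg amounts are drawn
lognormally (pesticide use is heavy-tailed, spanning orders of
magnitude); LD50 ranges are per category, insecticides far more
bee-toxic than fungicides or herbicides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from beeload import reclass
from beeload.area import CENSUS_YEARS, HA_PER_ACRE
from beeload.keys import (
    CROP_GROUPS,
    CompoundKey,
    CropKey,
    LandCoverKey,
    write_key,
)
from beeload.rates import UG_PER_KG


class SimulationError(ValueError):
    pass


def _default_compound_counts() -> dict[str, int]:
    return {"insecticide": 6, "fungicide": 3, "herbicide": 3}


def _default_ld50_ranges() -> dict[str, tuple[float, float]]:
    # insecticides span orders of magnitude down to high-toxicity actives;
    # fungicide/herbicide acute values cluster near the 100 ug/bee limit dose
    return {
        "insecticide": (0.01, 50.0),
        "fungicide": (20.0, 200.0),
        "herbicide": (20.0, 200.0),
    }


def _default_class_mix() -> dict[int, float]:
    # CDL-style codes: row crops, a wheat/soybean double crop, an
    # unsurveyed crop (oats), and two non-crop classes
    return {1: 0.30, 5: 0.20, 24: 0.10, 36: 0.05, 26: 0.05, 28: 0.05, 121: 0.05, 141: 0.20}


@dataclass
class SimConfig:
    """Study conditions for one synthetic bundle."""

    seed: int = 0
    n_states: int = 3
    groups: tuple[str, ...] = CROP_GROUPS
    n_compounds_per_category: dict[str, int] = field(default_factory=_default_compound_counts)
    years: tuple[int, int] = (1997, 2002)  # inclusive; endpoints census years
    missing_rate_use: float = 0.10
    missing_rate_area: float = 0.10
    use_magnitude: tuple[float, float] = (9.0, 1.5)  # ln-kg location, spread
    ld50_ranges: dict[str, tuple[float, float]] = field(default_factory=_default_ld50_ranges)
    raster_size: tuple[int, int] = (60, 60)
    class_mix: dict[int, float] = field(default_factory=_default_class_mix)

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise SimulationError("n_states must be >= 1")
        if sum(self.n_compounds_per_category.values()) < 1:
            raise SimulationError("need at least one compound")
        unknown = set(self.groups) - set(CROP_GROUPS)
        if unknown:
            raise SimulationError(f"unknown crop groups: {sorted(unknown)}")
        if not 0 <= self.missing_rate_use < 1 or not 0 <= self.missing_rate_area < 1:
            raise SimulationError("missing rates must lie in [0, 1)")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise SimulationError("class_mix frequencies must sum to 1")
        for cat, (lo, hi) in self.ld50_ranges.items():
            if not 0 < lo <= hi:
                raise SimulationError(f"invalid LD50 range for {cat}")
        if self.years[1] < self.years[0]:
            raise SimulationError("years range reversed")


@dataclass
class GroundTruth:
    """Exact quantities the generated files encode."""

    true_hectares: pd.DataFrame  # state, usgs_crop_group, year, hectares
    true_rates: pd.DataFrame  # compound, state, usgs_crop_group, year, kg_per_ha (low)
    true_loads: pd.DataFrame  # state, usgs_crop_group, year, three load measures
    true_ld50: pd.DataFrame  # compound, category, ld50_contact_ug_bee, ld50_oral_ug_bee
    true_class_counts: dict[int, int]


@dataclass
class FixtureBundle:
    """Paths of one generated bundle."""

    directory: Path
    crop_key: Path
    compound_key: Path
    landcover_key: Path
    use: Path
    census: Path
    survey: Path
    ecotox: Path
    ppdb: Path
    raster: Path


def _make_casrn(index: int) -> str:
    body = f"{100000 + index}-{10 + index % 80:02d}"
    digits = [int(c) for c in body.replace("-", "")]
    check = sum(w * d for w, d in enumerate(reversed(digits), start=1)) % 10
    return f"{body}-{check}"


def _state_names(n: int) -> list[str]:
    return [f"STATE {i + 1:02d}" for i in range(n)]


#: Default land-cover key matching ``_default_class_mix`` codes.
def default_landcover_key() -> list[LandCoverKey]:
    return [
        LandCoverKey(1, "Corn", "single_crop", ("corn",), 1),
        LandCoverKey(5, "Soybeans", "single_crop", ("soybeans",), 1),
        LandCoverKey(24, "Winter Wheat", "single_crop", ("wheat",), 1),
        LandCoverKey(36, "Alfalfa", "single_crop", ("alfalfa",), 1),
        LandCoverKey(26, "Dbl Crop WinWht/Soybeans", "double_crop", ("wheat", "soybeans"), 2),
        LandCoverKey(28, "Oats", "single_crop", ("other_crops",), 0),
        LandCoverKey(121, "Developed/Open Space", "noncrop", (), 0),
        LandCoverKey(141, "Deciduous Forest", "noncrop", (), 0),
    ]


def generate_fixture_bundle(
    config: SimConfig, out_dir: str | Path
) -> tuple[FixtureBundle, GroundTruth]:
    """Write a complete fixture bundle and return its exact ground truth.

    Deterministic for a fixed config: same seed, byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    states = _state_names(config.n_states)
    y0, y1 = config.years
    years = list(range(y0, y1 + 1))

    # ---- crosswalk keys -------------------------------------------------
    crop_keys: list[CropKey] = []
    crops_of_group: dict[str, list[str]] = {}
    for group in config.groups:
        names = [f"{group.upper().replace('_', ' ')} CROP {c}" for c in ("A", "B")]
        crops_of_group[group] = names
        item = "bearing_nonbearing_acres" if group == "orchards_grapes" else "harvested_acres"
        for name in names:
            crop_keys.append(CropKey(name, group, item))

    compound_keys: list[CompoundKey] = []
    idx = 0
    for category, count in config.n_compounds_per_category.items():
        for i in range(count):
            idx += 1
            compound_keys.append(
                CompoundKey(
                    usgs_name=f"{category[:5].upper()}-{i + 1:02d}",
                    casrn=_make_casrn(idx),
                    category=category,
                    moa_group=f"{category[0].upper()}{i % 3 + 1}",
                    usda_name=f"{category[:5].upper()}-{i + 1:02d} USDA",
                )
            )
    landcover_keys = default_landcover_key()

    # ---- crop area: linear-in-year series, census + gapped survey -------
    area_rows = []
    hect_truth: dict[tuple[str, str, int], float] = {}
    droppable = [y for y in years[1:-1] if y not in CENSUS_YEARS]
    for state in states:
        for group in config.groups:
            for crop in crops_of_group[group]:
                base = float(rng.uniform(2e3, 5e4))
                slope = float(rng.uniform(-0.02, 0.03)) * base
                dropped = {
                    y for y in droppable if rng.random() < config.missing_rate_area
                }
                for year in years:
                    ha = base + slope * (year - y0)
                    hect_truth[(state, group, year)] = (
                        hect_truth.get((state, group, year), 0.0) + ha
                    )
                    program = "CENSUS" if year in CENSUS_YEARS else "SURVEY"
                    if program == "SURVEY" and year in dropped:
                        continue
                    area_rows.append(
                        {
                            "program": program,
                            "state": state,
                            "commodity": crop,
                            "year": year,
                            "value": ha / HA_PER_ACRE,
                        }
                    )
    area_df = pd.DataFrame(area_rows)
    true_hectares = pd.DataFrame(
        [
            {"state": s, "usgs_crop_group": g, "year": y, "hectares": ha}
            for (s, g, y), ha in sorted(hect_truth.items())
        ]
    )

    # ---- toxicity: log-symmetric regulatory points + decoys -------------
    ld50_rows = []
    ecotox_rows = []
    ppdb_rows = []
    spread = 1.5
    for ck in compound_keys:
        lo, hi = config.ld50_ranges.get(ck.category, (1.0, 100.0))
        entry = {"compound": ck.usgs_name, "category": ck.category}
        for route in ("contact", "oral"):
            true = float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
            entry[f"ld50_{route}_ug_bee"] = true
            # the two regulatory points whose geometric mean is the truth
            ecotox_rows.append(
                dict(
                    casrn=ck.casrn, route=route, value_ug_per_bee=true * spread,
                    qualifier="point", regulatory=True,
                    duration_value=48, duration_unit="h", life_stage="adult",
                )
            )
            ppdb_rows.append(
                dict(casrn=ck.casrn, route=route, value_ug_per_bee=true / spread,
                     qualifier="point")
            )
            # decoys the consensus rules must ignore or the filter remove
            ecotox_rows.extend(
                [
                    dict(  # non-regulatory point: out-tiered by regulatory points
                        casrn=ck.casrn, route=route, value_ug_per_bee=true * 3,
                        qualifier="point", regulatory=False,
                        duration_value=2, duration_unit="d", life_stage="adult",
                    ),
                    dict(  # censored bound: ignored when points exist
                        casrn=ck.casrn, route=route, value_ug_per_bee=true * 10,
                        qualifier="greater_than", regulatory=False,
                        duration_value=48, duration_unit="h", life_stage="adult",
                    ),
                    dict(  # larval record: removed by the adult filter
                        casrn=ck.casrn, route=route, value_ug_per_bee=true / 7,
                        qualifier="point", regulatory=True,
                        duration_value=2, duration_unit="d", life_stage="larva",
                    ),
                    dict(  # chronic record: removed by the <=4-day filter
                        casrn=ck.casrn, route=route, value_ug_per_bee=true / 9,
                        qualifier="point", regulatory=True,
                        duration_value=10, duration_unit="d", life_stage="adult",
                    ),
                ]
            )
        ecotox_rows.append(
            dict(  # non-contact/oral route: removed by the route filter
                casrn=ck.casrn, route="other", value_ug_per_bee=1.0,
                qualifier="point", regulatory=False,
                duration_value=48, duration_unit="h", life_stage="adult",
            )
        )
        ld50_rows.append(entry)
    true_ld50 = pd.DataFrame(ld50_rows)

    # ---- pesticide use and derived truth --------------------------------
    mu, sigma = config.use_magnitude
    use_rows = []
    rate_rows = []
    load_acc: dict[tuple[str, str, int], list[float]] = {}
    ld50_of = {r["compound"]: r for r in ld50_rows}
    for ck in compound_keys:
        for state in states:
            for group in config.groups:
                for year in years:
                    if rng.random() < config.missing_rate_use:
                        continue
                    kg_high = float(rng.lognormal(mu, sigma))
                    kg_low = kg_high * float(rng.uniform(0.6, 1.0))
                    use_rows.append(
                        {
                            "compound": ck.usgs_name,
                            "state": state,
                            "usgs_crop_group": group,
                            "year": year,
                            "kg_low": kg_low,
                            "kg_high": kg_high,
                        }
                    )
                    ha = hect_truth[(state, group, year)]
                    rate = kg_low / ha
                    rate_rows.append(
                        {
                            "compound": ck.usgs_name,
                            "state": state,
                            "usgs_crop_group": group,
                            "year": year,
                            "kg_per_ha": rate,
                        }
                    )
                    if ck.category == "insecticide":
                        acc = load_acc.setdefault((state, group, year), [0.0, 0.0, 0.0])
                        acc[0] += rate
                        acc[1] += rate * UG_PER_KG / ld50_of[ck.usgs_name]["ld50_contact_ug_bee"]
                        acc[2] += rate * UG_PER_KG / ld50_of[ck.usgs_name]["ld50_oral_ug_bee"]
    use_df = pd.DataFrame(use_rows)
    true_rates = pd.DataFrame(rate_rows)
    true_loads = pd.DataFrame(
        [
            {
                "state": s,
                "usgs_crop_group": g,
                "year": y,
                "insecticide_kg_per_ha": kg,
                "lethal_doses_per_ha_contact": c,
                "lethal_doses_per_ha_oral": o,
            }
            for (s, g, y), (kg, c, o) in sorted(load_acc.items())
        ]
    )

    # ---- land-cover raster ----------------------------------------------
    codes = np.array(sorted(config.class_mix), dtype=np.uint16)
    freqs = np.array([config.class_mix[int(c)] for c in codes])
    n_cells = config.raster_size[0] * config.raster_size[1]
    grid = rng.choice(codes, size=n_cells, p=freqs).reshape(config.raster_size)
    values, counts = np.unique(grid, return_counts=True)
    class_counts = {int(v): int(c) for v, c in zip(values, counts)}
    raster = reclass.Raster(
        data=grid.astype(np.uint16),
        pixel_scale=(30.0, 30.0, 0.0),
        tiepoint=(0, 0, 0, 500000.0, 4500000.0, 0.0),
    )

    # ---- write everything ------------------------------------------------
    bundle = FixtureBundle(
        directory=out,
        crop_key=out / "crop_key.csv",
        compound_key=out / "compound_key.csv",
        landcover_key=out / "landcover_key.csv",
        use=out / "use_kg.csv",
        census=out / "area_census.csv",
        survey=out / "area_survey.csv",
        ecotox=out / "tox_ecotox.csv",
        ppdb=out / "tox_ppdb.csv",
        raster=out / "landcover.tif",
    )
    write_key(crop_keys, bundle.crop_key)
    write_key(compound_keys, bundle.compound_key)
    write_key(landcover_keys, bundle.landcover_key)
    use_df.to_csv(bundle.use, index=False)
    area_df[area_df["program"] == "CENSUS"].to_csv(bundle.census, index=False)
    area_df[area_df["program"] == "SURVEY"].to_csv(bundle.survey, index=False)
    pd.DataFrame(ecotox_rows).to_csv(bundle.ecotox, index=False)
    pd.DataFrame(ppdb_rows).to_csv(bundle.ppdb, index=False)
    reclass.write_geotiff(raster, bundle.raster)

    truth = GroundTruth(
        true_hectares=true_hectares,
        true_rates=true_rates,
        true_loads=true_loads,
        true_ld50=true_ld50,
        true_class_counts=class_counts,
    )
    true_hectares.to_csv(out / "truth_hectares.csv", index=False)
    true_rates.to_csv(out / "truth_rates.csv", index=False)
    true_loads.to_csv(out / "truth_loads.csv", index=False)
    true_ld50.to_csv(out / "truth_ld50.csv", index=False)
    pd.DataFrame(
        {"cdl_code": list(class_counts), "cells": list(class_counts.values())}
    ).to_csv(out / "truth_class_counts.csv", index=False)
    return bundle, truth


def generate_validation_pairs(
    seed: int,
    n: int = 300,
    bias: float = 1.0,
    noise_sd: float = 0.0,
    n_outliers: int = 0,
    outlier_factor: float = 25.0,
) -> tuple[pd.DataFrame, dict]:
    """Paired pipeline/reference estimates with controlled disagreement.

    ``est_a = bias * est_b * exp(noise)`` with lognormal base magnitudes
    and optional planted outlier pairs (tagged, and attributed to a fixed
    compound-crop combination so exclusion lists can target them).
    """
    if noise_sd < 0:
        raise SimulationError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    crops = ["CORN", "SOYBEANS", "WHEAT", "COTTON", "RICE"]
    categories = ["insecticide", "fungicide", "herbicide"]
    est_b = rng.lognormal(mean=2.0, sigma=1.0, size=n)
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    est_a = bias * est_b * np.exp(noise)
    df = pd.DataFrame(
        {
            "state": [f"STATE {i % 7 + 1:02d}" for i in range(n)],
            "crop": [crops[i % len(crops)] for i in range(n)],
            "year": [1997 + i % 21 for i in range(n)],
            "compound": [f"CMPD-{i % 40 + 1:03d}" for i in range(n)],
            "category": [categories[i % 3] for i in range(n)],
            "est_a": est_a,
            "est_b": est_b,
            "pct_area_treated": rng.uniform(1.0, 100.0, size=n),
            "is_outlier": False,
        }
    )
    if n_outliers:
        pick = rng.choice(n, size=min(n_outliers, n), replace=False)
        df.loc[pick, "est_a"] = df.loc[pick, "est_a"] * outlier_factor
        df.loc[pick, "compound"] = "OUTLIER-CMPD"
        df.loc[pick, "crop"] = "COTTON"
        df.loc[pick, "is_outlier"] = True
    params = {"bias": bias, "noise_sd": noise_sd, "n_outliers": int(n_outliers)}
    return df, params
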