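"""Consensus acute honey-bee LD50 values from heterogeneous endpoint tables.

Acute contact and oral LD50 endpoints for the honey bee (*Apis mellifera*)
come from two kinds of sources: a large toxicology database export mixing
point estimates, censored bounds (">x", "<x"), exposure durations, routes
and life stages; and a curated properties database of regulatory values.
This module standardizes them, filters to acute (<= 4 day) adult contact or
oral records, and resolves one consensus LD50 per compound and route:

1. point estimates beat censored bounds, always;
2. among points, regulatory (US-EPA / E.U.) estimates are preferred when
   present; the consensus is the geometric mean of the preferred tier;
3. with only bounds, "<x" values resolve to their minimum (conservative:
   a lower LD50 means more toxic), else ">x" values to their maximum;
4. compounds with no usable endpoint receive the median consensus value of
   their mode-of-action group, and failing that the median over all
   resolved insecticides.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from beeload.keys import CompoundKey, normalize_name

logger = logging.getLogger(__name__)

ROUTES = ("contact", "oral")
QUALIFIERS = ("point", "greater_than", "less_than")

#: Exposure duration (days) at or below which an endpoint counts as acute.
ACUTE_MAX_DAYS = 4.0


class ToxicityError(ValueError):
    pass


@dataclass(frozen=True)
class ToxicityEndpoint:
    """One standardized LD50 record, in ug active ingredient per bee."""

    compound: str
    route: str  # contact | oral | other
    value_ug_per_bee: float
    qualifier: str  # point | greater_than | less_than
    regulatory: bool
    exposure_days: float
    life_stage: str  # adult | larva | other
    source: str  # ecotox | ppdb

    def __post_init__(self) -> None:
        if not self.value_ug_per_bee > 0:
            raise ToxicityError(
                f"non-positive LD50 {self.value_ug_per_bee!r} for {self.compound}"
            )
        if not self.exposure_days > 0:
            raise ToxicityError(
                f"non-positive exposure duration for {self.compound}"
            )
        if self.qualifier not in QUALIFIERS:
            raise ToxicityError(f"unknown qualifier {self.qualifier!r}")


@dataclass(frozen=True)
class ConsensusLD50:
    """Resolved LD50 for one compound and route, with its derivation basis."""

    compound: str
    route: str
    ld50_ug_per_bee: float
    basis: str  # point_consensus | bound_min | bound_max | moa_median | global_median
    n_endpoints_used: int
    mixed_bounds: bool = False  # both "<" and ">" bounds present, "<" used

    def __post_init__(self) -> None:
        if not self.ld50_ug_per_bee > 0:
            raise ToxicityError("consensus LD50 must be positive")
        if self.basis == "point_consensus" and self.n_endpoints_used < 1:
            raise ToxicityError("point consensus requires at least one endpoint")


def filter_acute_adult(endpoints: Iterable[ToxicityEndpoint]) -> list[ToxicityEndpoint]:
    """Keep acute (<= 4 days) adult contact/oral records only."""
    return [
        ep
        for ep in endpoints
        if ep.exposure_days <= ACUTE_MAX_DAYS
        and ep.life_stage == "adult"
        and ep.route in ROUTES
    ]


def geometric_mean(values: Sequence[float]) -> float:
    """exp(mean(log x)); log-space form avoids product overflow/underflow."""
    if not values:
        raise ValueError("geometric mean of an empty sequence")
    return math.exp(sum(math.log(v) for v in values) / len(values))


def consensus_for_compound(
    endpoints: Sequence[ToxicityEndpoint], route: str
) -> ConsensusLD50 | None:
    """Resolve one compound's consensus LD50 for one route.

    ``endpoints`` must already be acute/adult-filtered and belong to a single
    compound.  Returns ``None`` when no endpoint of the requested route
    exists (unresolved; see :func:`impute_unresolved`).
    """
    if route not in ROUTES:
        raise ValueError(f"route must be one of {ROUTES}, got {route!r}")
    eps = [ep for ep in endpoints if ep.route == route]
    if not eps:
        return None
    compound = eps[0].compound

    points = [ep for ep in eps if ep.qualifier == "point"]
    if points:
        tier = [ep for ep in points if ep.regulatory] or points
        return ConsensusLD50(
            compound=compound,
            route=route,
            ld50_ug_per_bee=geometric_mean([ep.value_ug_per_bee for ep in tier]),
            basis="point_consensus",
            n_endpoints_used=len(tier),
        )

    less = [ep.value_ug_per_bee for ep in eps if ep.qualifier == "less_than"]
    greater = [ep.value_ug_per_bee for ep in eps if ep.qualifier == "greater_than"]
    if less:
        return ConsensusLD50(
            compound=compound,
            route=route,
            ld50_ug_per_bee=min(less),
            basis="bound_min",
            n_endpoints_used=len(less),
            mixed_bounds=bool(greater),
        )
    return ConsensusLD50(
        compound=compound,
        route=route,
        ld50_ug_per_bee=max(greater),
        basis="bound_max",
        n_endpoints_used=len(greater),
    )


def _median(values: Sequence[float]) -> float:
    # midpoint-of-middle-two convention for even counts
    return float(np.median(np.asarray(values, dtype=float)))


def impute_unresolved(
    consensus: Sequence[ConsensusLD50],
    compound_key: Sequence[CompoundKey],
    route: str,
) -> list[ConsensusLD50]:
    """Complete a partially resolved consensus table over every keyed compound.

    Unresolved compounds take the median consensus LD50 of resolved
    compounds in their mode-of-action group; if the group has none, the
    median over all resolved insecticides (falling back to all resolved
    compounds when no insecticide is resolved).  Output order follows the
    compound key.
    """
    resolved = {c.compound: c for c in consensus if c.route == route}
    if not resolved and any(
        ck.usgs_name not in resolved for ck in compound_key
    ):
        raise ToxicityError("cannot impute from empty set: no resolved compounds")

    by_moa: dict[str, list[float]] = {}
    category_of = {ck.usgs_name: ck.category for ck in compound_key}
    moa_of = {ck.usgs_name: ck.moa_group for ck in compound_key}
    for name, cons in resolved.items():
        moa = moa_of.get(name)
        if moa is not None:
            by_moa.setdefault(moa, []).append(cons.ld50_ug_per_bee)
    insecticide_values = [
        cons.ld50_ug_per_bee
        for name, cons in resolved.items()
        if category_of.get(name) == "insecticide"
    ]
    global_pool = insecticide_values or [c.ld50_ug_per_bee for c in resolved.values()]

    out: list[ConsensusLD50] = []
    for ck in compound_key:
        if ck.usgs_name in resolved:
            out.append(resolved[ck.usgs_name])
            continue
        group_values = by_moa.get(ck.moa_group, [])
        if group_values:
            value, basis = _median(group_values), "moa_median"
        else:
            value, basis = _median(global_pool), "global_median"
        out.append(
            ConsensusLD50(
                compound=ck.usgs_name,
                route=route,
                ld50_ug_per_bee=value,
                basis=basis,
                n_endpoints_used=0,
            )
        )
    return out


# ---------------------------------------------------------------------------
# File-level assembly


def read_ecotox_endpoints(path: str | Path) -> list[tuple[str, ToxicityEndpoint]]:
    """Read an ECOTOX-style export; returns (casrn, endpoint) pairs.

    Expected columns: casrn, route, value_ug_per_bee, qualifier, regulatory,
    duration_value, duration_unit (``h`` or ``d``), life_stage.  Durations in
    hours are converted to days before the acute filter.
    """
    df = pd.read_csv(path, dtype=str)
    pairs = []
    for _, row in df.iterrows():
        duration = float(row["duration_value"])
        unit = row["duration_unit"].strip().lower()
        if unit in {"h", "hr", "hours"}:
            days = duration / 24.0
        elif unit in {"d", "day", "days"}:
            days = duration
        else:
            raise ToxicityError(f"unknown duration unit {unit!r} in {path}")
        pairs.append(
            (
                row["casrn"].strip(),
                ToxicityEndpoint(
                    compound="",  # resolved against the key later
                    route=row["route"].strip().lower(),
                    value_ug_per_bee=float(row["value_ug_per_bee"]),
                    qualifier=row["qualifier"].strip().lower(),
                    regulatory=row["regulatory"].strip().lower() in {"1", "true", "t"},
                    exposure_days=days,
                    life_stage=row["life_stage"].strip().lower(),
                    source="ecotox",
                ),
            )
        )
    return pairs


def read_ppdb_endpoints(path: str | Path) -> list[tuple[str, ToxicityEndpoint]]:
    """Read a PPDB-style table; returns (casrn, endpoint) pairs.

    Expected columns: casrn, route, value_ug_per_bee, qualifier.  PPDB
    entries are regulatory acute adult values by construction (48 h assays),
    so those fields are fixed.
    """
    df = pd.read_csv(path, dtype=str)
    pairs = []
    for _, row in df.iterrows():
        pairs.append(
            (
                row["casrn"].strip(),
                ToxicityEndpoint(
                    compound="",
                    route=row["route"].strip().lower(),
                    value_ug_per_bee=float(row["value_ug_per_bee"]),
                    qualifier=row["qualifier"].strip().lower(),
                    regulatory=True,
                    exposure_days=2.0,
                    life_stage="adult",
                    source="ppdb",
                ),
            )
        )
    return pairs


def build_ld50_table(
    raw_ecotox: str | Path,
    raw_ppdb: str | Path,
    compound_key: Sequence[CompoundKey],
) -> pd.DataFrame:
    """Build the complete two-route consensus LD50 table for a compound key.

    Endpoint compound names are resolved through CASRN; endpoints whose
    CASRN is absent from the key are excluded with a logged warning.
    Returns one row per compound with contact and oral LD50, basis and
    endpoint-count columns, in key order.
    """
    by_casrn = {ck.casrn: ck for ck in compound_key if ck.casrn}
    pairs = read_ecotox_endpoints(raw_ecotox) + read_ppdb_endpoints(raw_ppdb)

    endpoints: dict[str, list[ToxicityEndpoint]] = {}
    unmatched: set[str] = set()
    for casrn, ep in pairs:
        ck = by_casrn.get(casrn)
        if ck is None:
            unmatched.add(casrn)
            continue
        endpoints.setdefault(ck.usgs_name, []).append(replace(ep, compound=ck.usgs_name))
    if unmatched:
        logger.warning(
            "excluded endpoints for %d CASRN(s) absent from compound key: %s",
            len(unmatched),
            sorted(unmatched),
        )

    rows: dict[str, dict] = {
        ck.usgs_name: {"compound": ck.usgs_name, "casrn": ck.casrn, "category": ck.category}
        for ck in compound_key
    }
    for route in ROUTES:
        partial = []
        for name, eps in endpoints.items():
            cons = consensus_for_compound(filter_acute_adult(eps), route)
            if cons is not None:
                partial.append(cons)
        complete = impute_unresolved(partial, compound_key, route)
        for cons in complete:
            row = rows[cons.compound]
            row[f"ld50_{route}_ug_bee"] = cons.ld50_ug_per_bee
            row[f"basis_{route}"] = cons.basis
            row[f"n_{route}"] = cons.n_endpoints_used
    return pd.DataFrame(rows.values())


def ld50_category_summary(table: pd.DataFrame, route: str = "contact") -> pd.DataFrame:
    """Median and IQR of consensus LD50 by compound category.

    Works on any table of the shape written by :func:`build_ld50_table`
    (including user-supplied deposited files with matching columns).
    """
    col = f"ld50_{route}_ug_bee"
    grouped = table.groupby("category")[col]
    return pd.DataFrame(
        {
            "n": grouped.size(),
            "median": grouped.median(),
            "q25": grouped.quantile(0.25),
            "q75": grouped.quantile(0.75),
        }
    ).reset_index()
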