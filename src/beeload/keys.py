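"""Controlled vocabularies and crosswalk keys joining the source datasets.

Five key families tie the use, area, toxicity, and land-cover sources
together: USDA crop names -> USGS crop groups, compound names -> CAS
registry numbers -> category/mode-of-action, and crop groups -> land-cover
class codes.  Keys are plain CSV files; loaders validate types and
invariants at read time so that join failures surface early rather than as
silent row loss downstream.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

#: The ten crop groups at which pesticide use is reported.
CROP_GROUPS: tuple[str, ...] = (
    "alfalfa",
    "corn",
    "cotton",
    "orchards_grapes",
    "other_crops",
    "pasture_hay",
    "rice",
    "soybeans",
    "vegetables_fruit",
    "wheat",
)

#: Acreage items used per crop kind: harvested acres for annual/hay crops,
#: bearing & non-bearing acres for tree crops.
AREA_ITEMS: tuple[str, ...] = ("harvested_acres", "bearing_nonbearing_acres")

COMPOUND_CATEGORIES: tuple[str, ...] = ("insecticide", "fungicide", "herbicide", "other")

LANDCOVER_KINDS: tuple[str, ...] = ("single_crop", "double_crop", "noncrop")

#: Mean adult honey-bee worker body mass, mg.  Documented for users who wish
#: to rescale lethal doses to other bee species by body weight; it is not
#: applied anywhere in this package.
HONEY_BEE_WORKER_MASS_MG: float = 120.0

_WS = re.compile(r"\s+")


class KeyValidationError(ValueError):
    """A key CSV violates the schema or an invariant of its key kind."""


def normalize_name(name: str) -> str:
    """Canonical join form of a name: upper-case, trimmed, whitespace collapsed.

    The three source vocabularies differ in case and spacing, so every join
    key passes through this before matching.
    """
    return _WS.sub(" ", name.strip()).upper()


def cas_checksum_valid(casrn: str) -> bool:
    """Validate a CAS registry number's format and check digit.

    The check digit is the weighted sum of the other digits (weights 1..n
    from the right) modulo 10.
    """
    if not re.fullmatch(r"\d{2,7}-\d{2}-\d", casrn):
        return False
    digits = [int(c) for c in casrn.replace("-", "")]
    body, check = digits[:-1], digits[-1]
    total = sum(w * d for w, d in enumerate(reversed(body), start=1))
    return total % 10 == check


@dataclass(frozen=True)
class CropKey:
    """Maps one USDA crop name to its USGS crop group and acreage item."""

    usda_crop_name: str
    usgs_crop_group: str | None
    area_item: str
    california_only: bool = False

    def __post_init__(self) -> None:
        if self.usgs_crop_group is not None and self.usgs_crop_group not in CROP_GROUPS:
            raise KeyValidationError(
                f"unknown usgs_crop_group {self.usgs_crop_group!r} "
                f"for crop {self.usda_crop_name!r}"
            )
        if self.area_item not in AREA_ITEMS:
            raise KeyValidationError(
                f"unknown area_item {self.area_item!r} for crop {self.usda_crop_name!r}"
            )


@dataclass(frozen=True)
class CompoundKey:
    """Maps one USGS active-ingredient name to CASRN, category and MoA group."""

    usgs_name: str
    casrn: str | None
    category: str
    moa_group: str
    usda_name: str | None = None

    def __post_init__(self) -> None:
        if self.category not in COMPOUND_CATEGORIES:
            raise KeyValidationError(
                f"unknown category {self.category!r} for compound {self.usgs_name!r}"
            )
        if self.casrn is not None and not cas_checksum_valid(self.casrn):
            raise KeyValidationError(
                f"CASRN {self.casrn!r} for compound {self.usgs_name!r} "
                "fails format/check-digit validation"
            )


@dataclass(frozen=True)
class LandCoverKey:
    """Maps one land-cover class code to its crop-group composition.

    ``component_groups`` lists the crop groups of the class components, with
    surveyed components first; ``surveyed_components`` counts how many of
    them are covered by the pesticide use survey.  Double-crop classes have
    two components, non-crop classes none.
    """

    cdl_code: int
    cdl_name: str
    kind: str
    component_groups: tuple[str, ...] = field(default_factory=tuple)
    surveyed_components: int = 0
    california_variant: bool = False

    def __post_init__(self) -> None:
        if self.kind not in LANDCOVER_KINDS:
            raise KeyValidationError(
                f"unknown land-cover kind {self.kind!r} for code {self.cdl_code}"
            )
        expected = {"single_crop": 1, "double_crop": 2, "noncrop": 0}[self.kind]
        if len(self.component_groups) != expected:
            raise KeyValidationError(
                f"{self.kind} code {self.cdl_code} must have {expected} "
                f"component group(s), got {len(self.component_groups)}"
            )
        if not 0 <= self.surveyed_components <= len(self.component_groups):
            raise KeyValidationError(
                f"surveyed_components {self.surveyed_components} out of range "
                f"for code {self.cdl_code}"
            )


_KEY_TYPES = {"crop": CropKey, "compound": CompoundKey, "landcover": LandCoverKey}

_HEADERS = {
    "crop": ["usda_crop_name", "usgs_crop_group", "area_item", "california_only"],
    "compound": ["usgs_name", "casrn", "category", "moa_group", "usda_name"],
    "landcover": [
        "cdl_code",
        "cdl_name",
        "kind",
        "component_groups",
        "surveyed_components",
        "california_variant",
    ],
}

_PRIMARY = {"crop": "usda_crop_name", "compound": "usgs_name", "landcover": "cdl_code"}


def _parse_bool(text: str) -> bool:
    return text.strip().lower() in {"1", "true", "t", "yes"}


def _row_to_record(kind: str, row: dict[str, str], line: int):
    try:
        if kind == "crop":
            group = row["usgs_crop_group"].strip()
            return CropKey(
                usda_crop_name=normalize_name(row["usda_crop_name"]),
                usgs_crop_group=group.lower() or None,
                area_item=row["area_item"].strip().lower(),
                california_only=_parse_bool(row.get("california_only", "")),
            )
        if kind == "compound":
            casrn = row["casrn"].strip()
            usda = row.get("usda_name", "").strip()
            return CompoundKey(
                usgs_name=normalize_name(row["usgs_name"]),
                casrn=casrn or None,
                category=row["category"].strip().lower(),
                moa_group=row["moa_group"].strip(),
                usda_name=normalize_name(usda) if usda else None,
            )
        groups = tuple(
            g.strip().lower() for g in row["component_groups"].split(";") if g.strip()
        )
        return LandCoverKey(
            cdl_code=int(row["cdl_code"]),
            cdl_name=row["cdl_name"].strip(),
            kind=row["kind"].strip().lower(),
            component_groups=groups,
            surveyed_components=int(row["surveyed_components"] or 0),
            california_variant=_parse_bool(row.get("california_variant", "")),
        )
    except KeyValidationError as exc:
        raise KeyValidationError(f"row {line}: {exc}") from None
    except (KeyError, ValueError) as exc:
        raise KeyValidationError(f"row {line}: malformed key row ({exc})") from None


def load_key(path: str | Path, key_kind: str) -> list:
    """Load and validate one key CSV.

    Parameters
    ----------
    path:
        CSV with the documented header for ``key_kind``.
    key_kind:
        One of ``"crop"``, ``"compound"``, ``"landcover"``.

    Raises
    ------
    KeyValidationError
        On duplicate primary names (naming the duplicates), unknown enum
        values (naming the row), or malformed rows.
    """
    if key_kind not in _KEY_TYPES:
        raise ValueError(f"unknown key kind {key_kind!r}")
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_HEADERS[key_kind]) - set(reader.fieldnames or [])
        # usda_name / california flags are optional columns
        missing -= {"usda_name", "california_only", "california_variant"}
        if missing:
            raise KeyValidationError(f"{path}: missing columns {sorted(missing)}")
        for line, row in enumerate(reader, start=2):
            records.append(_row_to_record(key_kind, row, line))

    primary = _PRIMARY[key_kind]
    seen: dict = {}
    dupes = []
    for rec in records:
        name = getattr(rec, primary)
        if name in seen:
            dupes.append(name)
        seen[name] = rec
    if dupes:
        raise KeyValidationError(
            f"duplicate {primary} value(s) in {path}: {sorted(set(map(str, dupes)))}"
        )
    return records


def write_key(records: Sequence, path: str | Path) -> None:
    """Write a key collection back to CSV (inverse of :func:`load_key`)."""
    if not records:
        raise ValueError("cannot infer key kind from an empty collection")
    kind = {CropKey: "crop", CompoundKey: "compound", LandCoverKey: "landcover"}[
        type(records[0])
    ]
    header = _HEADERS[kind]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec in records:
            row = []
            for col in header:
                val = getattr(rec, col)
                if col == "component_groups":
                    val = ";".join(val)
                elif val is None:
                    val = ""
                elif isinstance(val, bool):
                    val = str(val).lower()
                row.append(val)
            writer.writerow(row)


@dataclass
class CrosswalkReport:
    """Cross-key consistency findings; empty everywhere iff consistent."""

    compounds_without_casrn: list[str] = field(default_factory=list)
    compounds_without_usda_name: list[str] = field(default_factory=list)
    crops_without_group: list[str] = field(default_factory=list)
    landcover_unknown_groups: list[tuple[int, str]] = field(default_factory=list)

    def is_consistent(self) -> bool:
        return not (
            self.compounds_without_casrn
            or self.crops_without_group
            or self.landcover_unknown_groups
        )


def validate_crosswalk(
    crop_keys: Iterable[CropKey],
    compound_keys: Iterable[CompoundKey],
    landcover_keys: Iterable[LandCoverKey],
) -> CrosswalkReport:
    """Report cross-key inconsistencies without raising.

    Lists compounds lacking a CASRN (or a USDA name, informational only),
    crops lacking a group, and land-cover component groups outside the ten
    surveyed crop groups.
    """
    report = CrosswalkReport()
    for ck in compound_keys:
        if ck.casrn is None:
            report.compounds_without_casrn.append(ck.usgs_name)
        if ck.usda_name is None:
            report.compounds_without_usda_name.append(ck.usgs_name)
    for crop in crop_keys:
        if crop.usgs_crop_group is None:
            report.crops_without_group.append(crop.usda_crop_name)
    for lc in landcover_keys:
        for grp in lc.component_groups:
            if grp not in CROP_GROUPS:
                report.landcover_unknown_groups.append((lc.cdl_code, grp))
    return report
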