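"""Food-record data model and CSV food-table io.

Every classifier in this package consumes :class:`FoodRecord` objects whose
nutrient declarations are expressed per 100 g (solids) or per 100 mL
(liquids) of product as sold, the convention used on Chilean labels.

Units: energy in kcal and kJ (kJ derived as 4.184 x kcal when absent),
sugars / saturated fat / total fat / fibre / protein in g, sodium in mg,
fruit-vegetable-nut-legume content as a percentage 0-100.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

KJ_PER_KCAL = 4.184
#: mg of sodium per g of salt (NaCl is ~40% sodium by mass).
SODIUM_MG_PER_G_SALT = 400.0
#: relative tolerance for declared kJ vs 4.184 x declared kcal
ENERGY_RTOL = 0.02

GROUPS = ("cereals", "dairy", "protein_foods", "oils_fats", "sugars_others")
STATES = ("solid", "liquid")
SPECIAL_CATEGORIES = ("none", "beverage", "added_fat", "cheese")

#: required CSV header (energy_kj and salt_g are accepted as optional extras)
REQUIRED_COLUMNS = (
    "food_id", "name", "group", "state",
    "energy_kcal", "sugars_g", "saturated_fat_g", "total_fat_g",
    "sodium_mg", "fibre_g", "protein_g", "fvnl_pct",
    "added_sugar", "added_sat_fat", "added_sodium",
    "markers", "special_category",
)

NUTRIENT_FIELDS = (
    "energy_kcal", "sugars_g", "saturated_fat_g", "total_fat_g",
    "sodium_mg", "fibre_g", "protein_g", "fvnl_pct",
)


@dataclass(slots=True)
class NutrientPanel:
    """Declared composition per 100 g (solid) or 100 mL (liquid)."""

    energy_kcal: float
    sugars_g: float
    saturated_fat_g: float
    total_fat_g: float
    sodium_mg: float
    fibre_g: float
    protein_g: float
    fvnl_pct: float = 0.0
    energy_kj: float | None = None

    def __post_init__(self) -> None:
        if self.energy_kj is None and self.energy_kcal is not None:
            self.energy_kj = KJ_PER_KCAL * self.energy_kcal

    def scaled(self, factors: dict[str, float]) -> "NutrientPanel":
        """Return a copy with each nutrient multiplied by its factor (kJ rederived)."""
        values = {f: getattr(self, f) * factors.get(f, 1.0) for f in NUTRIENT_FIELDS}
        values["saturated_fat_g"] = min(values["saturated_fat_g"], values["total_fat_g"])
        values["fvnl_pct"] = min(values["fvnl_pct"], 100.0)
        return NutrientPanel(**values)


@dataclass(slots=True)
class FoodRecord:
    """One basket item: identity, food group, physical state, panel and flags."""

    food_id: str
    name: str
    group: str
    state: str
    panel: NutrientPanel
    added_sugar: bool = False
    added_sat_fat: bool = False
    added_sodium: bool = False
    markers: frozenset[str] = frozenset()
    special_category: str = "none"


@dataclass(frozen=True, slots=True)
class ValidationIssue:
    """A data problem found in one record; fatal issues block classification."""

    food_id: str
    field: str
    severity: str  # "warning" | "fatal"
    message: str

    @property
    def is_fatal(self) -> bool:
        return self.severity == "fatal"


class FoodTableError(ValueError):
    """File-level problem (missing column, or fatal rows under strict mode)."""


def _is_missing(x: float | None) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def validate_record(record: FoodRecord, vocabulary=None) -> list[ValidationIssue]:
    """Check all model invariants; an empty result means the record is
    classifiable by all three systems.

    If a marker ``vocabulary`` is given, marker tags outside its closed
    vocabulary are fatal.
    """
    issues: list[ValidationIssue] = []

    def fatal(f: str, msg: str) -> None:
        issues.append(ValidationIssue(record.food_id, f, "fatal", msg))

    if record.group not in GROUPS:
        fatal("group", f"unknown group {record.group!r}")
    if record.state not in STATES:
        fatal("state", f"unknown state {record.state!r}")
    if record.special_category not in SPECIAL_CATEGORIES:
        fatal("special_category", f"unknown special_category {record.special_category!r}")

    p = record.panel
    for f in NUTRIENT_FIELDS:
        v = getattr(p, f)
        if _is_missing(v):
            fatal(f, "missing value")
        elif v < 0:
            fatal(f, f"negative value {v}")
    if not _is_missing(p.fvnl_pct) and p.fvnl_pct > 100:
        fatal("fvnl_pct", f"fvnl_pct {p.fvnl_pct} exceeds 100")
    if (not _is_missing(p.saturated_fat_g) and not _is_missing(p.total_fat_g)
            and p.saturated_fat_g > p.total_fat_g + 1e-9):
        fatal("saturated_fat_g",
              f"saturated fat {p.saturated_fat_g} exceeds total fat {p.total_fat_g}")
    if not _is_missing(p.energy_kj) and not _is_missing(p.energy_kcal):
        expected = KJ_PER_KCAL * p.energy_kcal
        if expected == 0:
            if p.energy_kj > 0:
                fatal("energy_kj", "energy_kj > 0 while energy_kcal = 0")
        elif abs(p.energy_kj - expected) / expected > ENERGY_RTOL:
            fatal("energy_kj",
                  f"energy_kj {p.energy_kj} inconsistent with "
                  f"{KJ_PER_KCAL} x {p.energy_kcal} kcal = {expected:.1f}")

    if vocabulary is not None:
        unknown = record.markers - vocabulary.all_tags
        if unknown:
            fatal("markers", f"unknown marker tag(s): {', '.join(sorted(unknown))}")
    return issues


def _parse_float(raw: str) -> float | None:
    raw = raw.strip()
    if raw == "":
        return None
    return float(raw)  # may raise ValueError


def _parse_flag(raw: str) -> bool:
    raw = raw.strip()
    if raw not in ("0", "1"):
        raise ValueError(f"flag must be 0 or 1, got {raw!r}")
    return raw == "1"


def _open(source) -> TextIO:
    if isinstance(source, (str, Path)):
        return open(source, newline="", encoding="utf-8")
    return source


def read_food_table(
    source,
    strict: bool = False,
    vocabulary=None,
) -> tuple[list[FoodRecord], list[ValidationIssue]]:
    """Read a food-table CSV into records plus validation issues.

    Rows with fatal issues are excluded (reported in the issue list) so the
    remaining records are classifiable; with ``strict=True`` any fatal row
    raises :class:`FoodTableError` instead. Record order is preserved.
    A missing ``fvnl_pct`` cell defaults to 0 with a warning; a ``salt_g``
    column, if present, backs an empty ``sodium_mg`` cell via
    sodium_mg = salt_g x 400.
    """
    fh = _open(source)
    reader = csv.DictReader(fh)
    if reader.fieldnames is None:
        raise FoodTableError("empty input: no header row")
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in reader.fieldnames]
    if missing_cols:
        raise FoodTableError(f"missing required column(s): {', '.join(missing_cols)}")

    records: list[FoodRecord] = []
    issues: list[ValidationIssue] = []
    for i, row in enumerate(reader):
        food_id = (row.get("food_id") or f"<row {i + 2}>").strip()
        row_issues: list[ValidationIssue] = []
        values: dict[str, float | None] = {}
        for f in NUTRIENT_FIELDS:
            try:
                values[f] = _parse_float(row[f])
            except ValueError:
                row_issues.append(ValidationIssue(
                    food_id, f, "fatal", f"non-numeric value {row[f]!r}"))
                values[f] = None
        if values.get("sodium_mg") is None and row.get("salt_g", "").strip():
            try:
                salt = _parse_float(row["salt_g"])
                if salt is not None:
                    values["sodium_mg"] = salt * SODIUM_MG_PER_G_SALT
            except ValueError:
                row_issues.append(ValidationIssue(
                    food_id, "salt_g", "fatal", f"non-numeric value {row['salt_g']!r}"))
        if values["fvnl_pct"] is None:
            values["fvnl_pct"] = 0.0
            row_issues.append(ValidationIssue(
                food_id, "fvnl_pct", "warning", "missing fvnl_pct defaulted to 0"))
        energy_kj: float | None = None
        if row.get("energy_kj", "").strip():
            try:
                energy_kj = _parse_float(row["energy_kj"])
            except ValueError:
                row_issues.append(ValidationIssue(
                    food_id, "energy_kj", "fatal", f"non-numeric value {row['energy_kj']!r}"))

        flags = {}
        for f in ("added_sugar", "added_sat_fat", "added_sodium"):
            try:
                flags[f] = _parse_flag(row[f])
            except ValueError as e:
                row_issues.append(ValidationIssue(food_id, f, "fatal", str(e)))
                flags[f] = False

        # missing required numerics (other than the defaulted fvnl) are fatal
        for f in NUTRIENT_FIELDS:
            if values[f] is None and not any(x.field == f for x in row_issues):
                row_issues.append(ValidationIssue(food_id, f, "fatal", "missing value"))

        markers = frozenset(
            t.strip() for t in (row.get("markers") or "").split(";") if t.strip())
        if not any(x.is_fatal for x in row_issues):
            panel = NutrientPanel(
                energy_kcal=values["energy_kcal"],
                sugars_g=values["sugars_g"],
                saturated_fat_g=values["saturated_fat_g"],
                total_fat_g=values["total_fat_g"],
                sodium_mg=values["sodium_mg"],
                fibre_g=values["fibre_g"],
                protein_g=values["protein_g"],
                fvnl_pct=values["fvnl_pct"],
                energy_kj=energy_kj,
            )
            record = FoodRecord(
                food_id=food_id,
                name=(row.get("name") or "").strip(),
                group=(row.get("group") or "").strip(),
                state=(row.get("state") or "").strip(),
                panel=panel,
                markers=markers,
                special_category=(row.get("special_category") or "none").strip() or "none",
                **flags,
            )
            row_issues.extend(validate_record(record, vocabulary=vocabulary))
            if not any(x.is_fatal for x in row_issues):
                records.append(record)
        issues.extend(row_issues)

    if strict and any(x.is_fatal for x in issues):
        bad = sorted({x.food_id for x in issues if x.is_fatal})
        raise FoodTableError(f"fatal issues in record(s): {', '.join(bad)}")
    if isinstance(source, (str, Path)):
        fh.close()
    return records, issues


def write_food_table(records: Iterable[FoodRecord], dest) -> None:
    """Write records as the canonical food-table CSV (round-trips with
    :func:`read_food_table`)."""
    close = False
    if isinstance(dest, (str, Path)):
        dest = open(dest, "w", newline="", encoding="utf-8")
        close = True
    cols = list(REQUIRED_COLUMNS) + ["energy_kj"]
    w = csv.DictWriter(dest, fieldnames=cols)
    w.writeheader()
    for r in records:
        p = r.panel
        w.writerow({
            "food_id": r.food_id,
            "name": r.name,
            "group": r.group,
            "state": r.state,
            "energy_kcal": repr(float(p.energy_kcal)),
            "sugars_g": repr(float(p.sugars_g)),
            "saturated_fat_g": repr(float(p.saturated_fat_g)),
            "total_fat_g": repr(float(p.total_fat_g)),
            "sodium_mg": repr(float(p.sodium_mg)),
            "fibre_g": repr(float(p.fibre_g)),
            "protein_g": repr(float(p.protein_g)),
            "fvnl_pct": repr(float(p.fvnl_pct)),
            "added_sugar": int(r.added_sugar),
            "added_sat_fat": int(r.added_sat_fat),
            "added_sodium": int(r.added_sodium),
            "markers": ";".join(sorted(r.markers)),
            "special_category": r.special_category,
            "energy_kj": repr(float(p.energy_kj)),
        })
    if close:
        dest.close()
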