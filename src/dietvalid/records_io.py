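"""Reading and writing the tabular artifacts of a dietary validation study.

All study inputs are delimited text files: food-record exports (one row per
consumed item), a per-100 g food-composition table, a food-code → food-group
map, and a participant roster.  Because app export schemas vary, column names
and locale conventions are abstracted behind a :class:`DialectConfig`; the
shipped default matches the fixture schema used throughout this package.

Invalid rows are never silently dropped: every parse returns row-numbered
diagnostics alongside the accepted entries, so parsed + rejected always
equals the number of input rows.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "Occasion",
    "IdentificationMode",
    "AmountUnit",
    "ReportedState",
    "Gender",
    "Education",
    "FoodRecordEntry",
    "FoodDescriptor",
    "Participant",
    "DialectConfig",
    "RowError",
    "ParseResult",
    "read_food_records",
    "write_food_records",
    "read_composition_table",
    "write_composition_table",
    "read_group_map",
    "write_group_map",
    "read_roster",
    "write_roster",
    "write_report",
    "WHEEL_OF_FIVE_GROUPS",
]

#: The 19 Wheel of Five food groups used to aggregate items.
WHEEL_OF_FIVE_GROUPS: tuple[str, ...] = (
    "Vegetables",
    "Fruit",
    "Added fats",
    "Fish",
    "Legumes",
    "Meat",
    "Eggs",
    "Nuts",
    "Milk and milk products",
    "Cheese",
    "Bread",
    "Cereal products",
    "Potatoes",
    "Drinks",
    "Sandwich spreads",
    "Soups",
    "Snacks",
    "Sauces",
    "Other",
)


class Occasion(str, enum.Enum):
    BREAKFAST = "breakfast"
    MIDDAY_MEAL = "midday_meal"
    EVENING_MEAL = "evening_meal"
    IN_BETWEEN = "in_between"
    SUPPLEMENT = "supplement"


#: Canonical within-day ordering of eating occasions.
OCCASION_ORDER: dict[Occasion, int] = {o: i for i, o in enumerate(Occasion)}


class IdentificationMode(str, enum.Enum):
    GENERIC_SEARCH = "generic_search"
    PREVIOUSLY_SELECTED = "previously_selected"
    BRANDED_SEARCH = "branded_search"
    BARCODE_SCAN = "barcode_scan"
    RECIPE = "recipe"
    ASSOCIATED_ITEM = "associated_item"
    SUPPLEMENT_ENTRY = "supplement_entry"


class AmountUnit(str, enum.Enum):
    GRAM = "gram"
    MILLILITER = "milliliter"
    HOUSEHOLD_MEASURE = "household_measure"
    NATURAL_UNIT = "natural_unit"
    COMMERCIAL_UNIT = "commercial_unit"
    RECIPE_FRACTION = "recipe_fraction"


class ReportedState(str, enum.Enum):
    AS_CONSUMED = "as_consumed"
    UNPREPARED = "unprepared"


class Gender(str, enum.Enum):
    MAN = "man"
    WOMAN = "woman"


class Education(str, enum.Enum):
    LOW = "low"
    MIDDLE = "middle"
    HIGH = "high"


@dataclass(frozen=True)
class FoodRecordEntry:
    """One consumed item on one day: who, when, what, how much, how prepared."""

    participant_id: str
    day_index: int
    occasion: Occasion
    food_code: str
    identification_mode: IdentificationMode
    amount_value: float
    amount_unit: AmountUnit
    unit_count: float = 1.0
    unit_name: Optional[str] = None
    clock_time: Optional[str] = None  # "HH:MM"
    place: Optional[str] = None
    preparation_method: Optional[str] = None
    fat_used_code: Optional[str] = None
    reported_state: ReportedState = ReportedState.AS_CONSUMED

    def __post_init__(self) -> None:
        if self.day_index < 1:
            raise ValueError(f"day_index must be positive, got {self.day_index}")
        if self.amount_value < 0:
            raise ValueError("negative amount")
        if self.unit_count <= 0:
            raise ValueError("unit_count must be > 0")
        if self.amount_unit is AmountUnit.RECIPE_FRACTION and not (
            0 < self.amount_value <= 1
        ):
            raise ValueError("recipe fraction must lie in (0, 1]")
        if (
            self.identification_mode is IdentificationMode.SUPPLEMENT_ENTRY
            and self.occasion is not Occasion.SUPPLEMENT
        ):
            raise ValueError("supplement entries must carry occasion=supplement")


@dataclass(frozen=True)
class FoodDescriptor:
    """Per-food metadata: conversion factors, group and per-100 g composition.

    ``edible_units`` lists the amount-unit names (``"gram"``, ``"milliliter"``
    or household/natural/commercial unit keys) for which the reported portion
    includes inedible parts; the edible fraction is applied only for those.
    """

    food_code: str
    food_group: Optional[str] = None
    is_branded: bool = False
    generic_parent: Optional[str] = None
    density_g_per_ml: Optional[float] = None
    edible_fraction: float = 1.0
    edible_units: frozenset[str] = frozenset()
    yield_factor_by_prep: Mapping[str, float] = field(default_factory=dict)
    fat_absorption_fraction: float = 0.0
    unit_weights_g: Mapping[str, float] = field(default_factory=dict)
    composition_per_100g: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.edible_fraction <= 1):
            raise ValueError(
                f"{self.food_code}: edible_fraction must lie in (0, 1]"
            )
        if not (0 <= self.fat_absorption_fraction < 1):
            raise ValueError(
                f"{self.food_code}: fat_absorption_fraction must lie in [0, 1)"
            )
        if self.is_branded and not self.generic_parent:
            raise ValueError(
                f"{self.food_code}: branded descriptor requires a generic_parent"
            )
        if "energy_kcal" not in self.composition_per_100g:
            raise ValueError(
                f"{self.food_code}: composition must include energy_kcal"
            )
        if self.density_g_per_ml is not None and self.density_g_per_ml <= 0:
            raise ValueError(f"{self.food_code}: density must be positive")
        for prep, yf in self.yield_factor_by_prep.items():
            if yf <= 0:
                raise ValueError(f"{self.food_code}: yield factor {prep} <= 0")


@dataclass(frozen=True)
class Participant:
    """Demographics used for BMR estimation, BMI, matching and stratification."""

    participant_id: str
    gender: Gender
    age_years: int
    height_m: float
    weight_kg: float
    education: Education

    def __post_init__(self) -> None:
        if not (18 <= self.age_years <= 79):
            raise ValueError(
                f"{self.participant_id}: age {self.age_years} outside survey "
                "bounds 18-79"
            )
        if self.height_m <= 0 or self.weight_kg <= 0:
            raise ValueError(f"{self.participant_id}: nonpositive body size")

    @property
    def bmi_kg_m2(self) -> float:
        return self.weight_kg / self.height_m**2

    @property
    def bmi_class(self) -> str:
        """Three analysis classes: <25, 25-30, >=30 kg/m2."""
        bmi = self.bmi_kg_m2
        if bmi < 25:
            return "<25"
        if bmi < 30:
            return "25-30"
        return ">=30"


# ---------------------------------------------------------------------------
# Dialect
# ---------------------------------------------------------------------------

#: canonical record-file column names (the fixture schema)
_RECORD_COLUMNS = (
    "participant_id",
    "day_index",
    "occasion",
    "clock_time",
    "place",
    "food_code",
    "identification_mode",
    "amount_value",
    "amount_unit",
    "unit_count",
    "unit_name",
    "preparation_method",
    "fat_used_code",
    "reported_state",
)


@dataclass(frozen=True)
class DialectConfig:
    """Column-name mapping and locale conventions of an export file.

    ``columns`` maps canonical field names to the file's header names;
    unmapped fields default to their canonical name.
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    delimiter: str = ","
    decimal_comma: bool = False

    def file_column(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


DEFAULT_DIALECT = DialectConfig()


@dataclass(frozen=True)
class RowError:
    row: int  # 1-based data row number
    message: str


@dataclass
class ParseResult:
    entries: list[FoodRecordEntry]
    errors: list[RowError]

    @property
    def n_input_rows(self) -> int:
        return len(self.entries) + len(self.errors)


def _parse_number(raw: object, dialect: DialectConfig) -> float:
    s = str(raw).strip()
    if dialect.decimal_comma:
        s = s.replace(",", ".")
    return float(s)


def _opt(raw: object) -> Optional[str]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    s = str(raw).strip()
    return s or None


def read_food_records(
    path: str | Path, dialect: DialectConfig = DEFAULT_DIALECT
) -> ParseResult:
    """Parse a food-record export into validated entries plus diagnostics.

    Entries are returned in canonical order (participant, day, occasion
    order, clock time); rejected rows are reported with their 1-based data
    row number and reason.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str)
    mandatory = (
        "participant_id",
        "day_index",
        "occasion",
        "food_code",
        "identification_mode",
        "amount_value",
        "amount_unit",
    )
    for canonical in mandatory:
        if dialect.file_column(canonical) not in df.columns:
            raise ValueError(
                f"{path}: missing mandatory column "
                f"{dialect.file_column(canonical)!r}"
            )

    entries: list[FoodRecordEntry] = []
    errors: list[RowError] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowmap = dict(zip(df.columns, row))

        def get(canonical: str) -> object:
            return rowmap.get(dialect.file_column(canonical))

        try:
            amount = _parse_number(get("amount_value"), dialect)
            if amount < 0:
                raise ValueError("negative amount")
            unit_count_raw = _opt(get("unit_count"))
            entry = FoodRecordEntry(
                participant_id=str(get("participant_id")).strip(),
                day_index=int(str(get("day_index"))),
                occasion=Occasion(str(get("occasion")).strip()),
                clock_time=_opt(get("clock_time")),
                place=_opt(get("place")),
                food_code=str(get("food_code")).strip(),
                identification_mode=IdentificationMode(
                    str(get("identification_mode")).strip()
                ),
                amount_value=amount,
                amount_unit=AmountUnit(str(get("amount_unit")).strip()),
                unit_count=(
                    _parse_number(unit_count_raw, dialect)
                    if unit_count_raw is not None
                    else 1.0
                ),
                unit_name=_opt(get("unit_name")),
                preparation_method=_opt(get("preparation_method")),
                fat_used_code=_opt(get("fat_used_code")),
                reported_state=ReportedState(
                    _opt(get("reported_state")) or "as_consumed"
                ),
            )
        except (ValueError, KeyError) as exc:
            errors.append(RowError(row=i, message=str(exc)))
            continue
        entries.append(entry)

    entries.sort(
        key=lambda e: (
            e.participant_id,
            e.day_index,
            OCCASION_ORDER[e.occasion],
            e.clock_time or "",
        )
    )
    return ParseResult(entries=entries, errors=errors)


def write_food_records(
    entries: Iterable[FoodRecordEntry],
    path: str | Path,
    dialect: DialectConfig = DEFAULT_DIALECT,
) -> None:
    rows = []
    for e in entries:
        rows.append(
            {
                dialect.file_column("participant_id"): e.participant_id,
                dialect.file_column("day_index"): e.day_index,
                dialect.file_column("occasion"): e.occasion.value,
                dialect.file_column("clock_time"): e.clock_time,
                dialect.file_column("place"): e.place,
                dialect.file_column("food_code"): e.food_code,
                dialect.file_column("identification_mode"): (
                    e.identification_mode.value
                ),
                dialect.file_column("amount_value"): e.amount_value,
                dialect.file_column("amount_unit"): e.amount_unit.value,
                dialect.file_column("unit_count"): e.unit_count,
                dialect.file_column("unit_name"): e.unit_name,
                dialect.file_column("preparation_method"): e.preparation_method,
                dialect.file_column("fat_used_code"): e.fat_used_code,
                dialect.file_column("reported_state"): e.reported_state.value,
            }
        )
    cols = [dialect.file_column(c) for c in _RECORD_COLUMNS]
    pd.DataFrame(rows, columns=cols).to_csv(
        path, sep=dialect.delimiter, index=False
    )


# ---------------------------------------------------------------------------
# Composition table
# ---------------------------------------------------------------------------

_COMPOSITION_META_COLUMNS = (
    "food_code",
    "food_group",
    "is_branded",
    "generic_parent",
    "density_g_per_ml",
    "edible_fraction",
    "edible_units",
    "yield_factors",
    "fat_absorption_fraction",
    "unit_weights",
)


def _parse_pair_map(raw: Optional[str]) -> dict[str, float]:
    """Parse ``"key:val;key:val"`` cells used for unit weights / yield factors."""
    if not raw:
        return {}
    out: dict[str, float] = {}
    for chunk in raw.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(":")
        out[key.strip()] = float(val)
    return out


def _format_pair_map(mapping: Mapping[str, float]) -> str:
    return ";".join(f"{k}:{v:g}" for k, v in sorted(mapping.items()))


def read_composition_table(
    path: str | Path, delimiter: str = "\t"
) -> dict[str, FoodDescriptor]:
    """Load a per-100 g composition table keyed by food code.

    Columns outside the fixed metadata set are treated as nutrient columns
    (per 100 g) and preserved pass-through; ``energy_kcal`` is mandatory.
    Duplicate food codes or invalid factors are fatal.
    """
    df = pd.read_csv(path, sep=delimiter, dtype={"food_code": str})
    if "food_code" not in df.columns:
        raise ValueError(f"{path}: missing food_code column")
    if df["food_code"].duplicated().any():
        dups = df.loc[df["food_code"].duplicated(), "food_code"].tolist()
        raise ValueError(f"{path}: duplicate food codes {dups}")
    nutrient_cols = [c for c in df.columns if c not in _COMPOSITION_META_COLUMNS]
    if "energy_kcal" not in nutrient_cols:
        raise ValueError(f"{path}: composition table lacks energy_kcal")

    descriptors: dict[str, FoodDescriptor] = {}
    for _, row in df.iterrows():
        comp = {
            c: float(row[c]) if pd.notna(row[c]) else 0.0 for c in nutrient_cols
        }
        edible_units_raw = row.get("edible_units")
        edible_units = frozenset(
            u.strip()
            for u in str(edible_units_raw).split("|")
            if pd.notna(edible_units_raw) and u.strip()
        )
        desc = FoodDescriptor(
            food_code=str(row["food_code"]),
            food_group=_opt(row.get("food_group")),
            is_branded=str(row.get("is_branded", "")).strip().lower()
            in ("true", "1", "yes"),
            generic_parent=_opt(row.get("generic_parent")),
            density_g_per_ml=(
                float(row["density_g_per_ml"])
                if "density_g_per_ml" in df.columns
                and pd.notna(row["density_g_per_ml"])
                else None
            ),
            edible_fraction=(
                float(row["edible_fraction"])
                if "edible_fraction" in df.columns
                and pd.notna(row["edible_fraction"])
                else 1.0
            ),
            edible_units=edible_units,
            yield_factor_by_prep=_parse_pair_map(_opt(row.get("yield_factors"))),
            fat_absorption_fraction=(
                float(row["fat_absorption_fraction"])
                if "fat_absorption_fraction" in df.columns
                and pd.notna(row["fat_absorption_fraction"])
                else 0.0
            ),
            unit_weights_g=_parse_pair_map(_opt(row.get("unit_weights"))),
            composition_per_100g=comp,
        )
        descriptors[desc.food_code] = desc
    return descriptors


def write_composition_table(
    descriptors: Mapping[str, FoodDescriptor],
    path: str | Path,
    delimiter: str = "\t",
) -> None:
    nutrient_cols: list[str] = []
    for d in descriptors.values():
        for n in d.composition_per_100g:
            if n not in nutrient_cols:
                nutrient_cols.append(n)
    rows = []
    for d in descriptors.values():
        row: dict[str, object] = {
            "food_code": d.food_code,
            "food_group": d.food_group,
            "is_branded": str(d.is_branded).lower(),
            "generic_parent": d.generic_parent,
            "density_g_per_ml": d.density_g_per_ml,
            "edible_fraction": d.edible_fraction,
            "edible_units": "|".join(sorted(d.edible_units)),
            "yield_factors": _format_pair_map(d.yield_factor_by_prep),
            "fat_absorption_fraction": d.fat_absorption_fraction,
            "unit_weights": _format_pair_map(d.unit_weights_g),
        }
        row.update(d.composition_per_100g)
        rows.append(row)
    cols = list(_COMPOSITION_META_COLUMNS) + nutrient_cols
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=delimiter, index=False)


def apply_group_map(
    descriptors: Mapping[str, FoodDescriptor], group_map: Mapping[str, str]
) -> dict[str, FoodDescriptor]:
    """Return descriptors with food groups set from a food-code → group map."""
    out = {}
    for code, desc in descriptors.items():
        group = group_map.get(code, desc.food_group)
        out[code] = replace(desc, food_group=group)
    return out


def read_group_map(path: str | Path, delimiter: str = "\t") -> dict[str, str]:
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    for col in ("food_code", "wheel_of_five_group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    unknown = set(df["wheel_of_five_group"]) - set(WHEEL_OF_FIVE_GROUPS)
    if unknown:
        raise ValueError(f"{path}: unknown food groups {sorted(unknown)}")
    return dict(zip(df["food_code"], df["wheel_of_five_group"]))


def write_group_map(
    group_map: Mapping[str, str], path: str | Path, delimiter: str = "\t"
) -> None:
    pd.DataFrame(
        sorted(group_map.items()), columns=["food_code", "wheel_of_five_group"]
    ).to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Roster
# ---------------------------------------------------------------------------

def read_roster(path: str | Path, delimiter: str = ",") -> list[Participant]:
    df = pd.read_csv(path, sep=delimiter, dtype={"participant_id": str})
    required = (
        "participant_id",
        "gender",
        "age_years",
        "height_m",
        "weight_kg",
        "education",
    )
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return [
        Participant(
            participant_id=str(row.participant_id),
            gender=Gender(row.gender),
            age_years=int(row.age_years),
            height_m=float(row.height_m),
            weight_kg=float(row.weight_kg),
            education=Education(row.education),
        )
        for row in df.itertuples(index=False)
    ]


def write_roster(
    participants: Iterable[Participant], path: str | Path, delimiter: str = ","
) -> None:
    pd.DataFrame(
        [
            {
                "participant_id": p.participant_id,
                "gender": p.gender.value,
                "age_years": p.age_years,
                "height_m": p.height_m,
                "weight_kg": p.weight_kg,
                "education": p.education.value,
            }
            for p in participants
        ]
    ).to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------

def _to_markdown(df: pd.DataFrame) -> str:
    cells = df.astype(object).where(pd.notna(df), "").astype(str)
    widths = [
        max(len(col), *(len(v) for v in cells[col]), 3) if len(cells) else len(col)
        for col in cells.columns
    ]
    header = "| " + " | ".join(
        c.ljust(w) for c, w in zip(cells.columns, widths)
    ) + " |"
    sep = "|" + "|".join("-" * (w + 2) for w in widths) + "|"
    lines = [header, sep]
    for _, row in cells.iterrows():
        lines.append(
            "| " + " | ".join(v.ljust(w) for v, w in zip(row, widths)) + " |"
        )
    return "\n".join(lines) + "\n"


def write_report(
    results: pd.DataFrame, path: str | Path, format: str = "csv"
) -> None:
    """Write a results table deterministically as CSV or Markdown.

    Column order follows the input frame; rendering a result set twice
    produces byte-identical files.
    """
    path = Path(path)
    if format == "csv":
        results.to_csv(path, index=False)
    elif format == "markdown":
        path.write_text(_to_markdown(results))
    else:
        raise ValueError(f"unknown report format {format!r}")
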