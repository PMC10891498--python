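"""Convert validated record entries into daily food-group and nutrient totals.

The per-item computation follows food-consumption-survey practice: the
reported portion is converted to grams as consumed by multiplying the portion
weight by the number of portions, then applying (where relevant) food density
(volumes), the edible fraction (portions reported including inedible parts),
the preparation yield factor (amounts reported as unprepared food), and fat
absorbed during preparation.  The yield factor is applied before fat
absorption, which acts on the as-consumed mass.

Daily totals are linear in the entries: grams per Wheel of Five group are
summed per participant-day, and nutrients accumulate as grams × per-gram
composition.  Dietary-supplement entries are excluded from group and
nutrient totals (they are only tallied as a recording mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .records_io import (
    AmountUnit,
    FoodDescriptor,
    FoodRecordEntry,
    IdentificationMode,
    Occasion,
    ReportedState,
)

__all__ = [
    "DailyIntake",
    "Recipe",
    "IntakeError",
    "FAT_USING_PREPARATIONS",
    "grams_consumed",
    "apply_fat_absorption",
    "disaggregate_recipe",
    "daily_totals",
]

#: Preparation methods in which added fat can be absorbed by the food.
FAT_USING_PREPARATIONS: frozenset[str] = frozenset(
    {"fried", "deep_fried", "stir_fried"}
)

#: 1 MJ in kilocalories (thermochemical convention used by food tables).
KCAL_PER_MJ = 239.006


class IntakeError(ValueError):
    """Raised when an entry cannot be converted to grams or totals."""


@dataclass
class Recipe:
    """A user-defined mixed dish: ingredient grams for the full recipe."""

    recipe_id: str
    ingredients: Sequence[tuple[str, float]]  # (food_code, grams in full recipe)

    def __post_init__(self) -> None:
        for code, grams in self.ingredients:
            if grams <= 0:
                raise ValueError(f"recipe {self.recipe_id}: {code} grams <= 0")


@dataclass
class DailyIntake:
    """Per participant-day totals: grams per food group and nutrient amounts."""

    participant_id: str
    day_index: int
    grams_by_group: dict[str, float] = field(default_factory=dict)
    nutrients: dict[str, float] = field(default_factory=dict)

    @property
    def energy_kcal(self) -> float:
        return self.nutrients.get("energy_kcal", 0.0)

    @property
    def total_grams(self) -> float:
        return sum(self.grams_by_group.values())


def grams_consumed(entry: FoodRecordEntry, desc: FoodDescriptor) -> float:
    """Grams as consumed for one entry.

    portion weight × number of portions, then × density for volumes,
    × edible fraction when the reported form includes inedible parts, and
    × yield factor when the amount was reported as unprepared food.
    """
    unit = entry.amount_unit
    if unit is AmountUnit.RECIPE_FRACTION:
        raise IntakeError(
            f"{entry.food_code}: recipe fractions must be disaggregated first"
        )
    if unit is AmountUnit.GRAM:
        grams = entry.amount_value * entry.unit_count
        unit_key = "gram"
    elif unit is AmountUnit.MILLILITER:
        density = desc.density_g_per_ml if desc.density_g_per_ml is not None else 1.0
        grams = entry.amount_value * entry.unit_count * density
        unit_key = "milliliter"
    else:
        unit_key = entry.unit_name or ""
        if unit_key not in desc.unit_weights_g:
            raise IntakeError(
                f"{entry.food_code}: unquantifiable portion "
                f"(unit {unit_key!r} has no weight)"
            )
        grams = entry.amount_value * entry.unit_count * desc.unit_weights_g[unit_key]

    if unit_key in desc.edible_units:
        grams *= desc.edible_fraction

    if entry.reported_state is ReportedState.UNPREPARED:
        prep = entry.preparation_method
        if prep is None or prep not in desc.yield_factor_by_prep:
            raise IntakeError(
                f"{entry.food_code}: unprepared amount with unknown "
                f"preparation method {prep!r}"
            )
        grams *= desc.yield_factor_by_prep[prep]

    return grams


def apply_fat_absorption(
    entry: FoodRecordEntry,
    desc: FoodDescriptor,
    grams_as_consumed: float,
    descriptors: Mapping[str, FoodDescriptor],
) -> Optional[tuple[str, float]]:
    """Absorbed preparation fat, as ``(fat_food_code, grams)``, or None.

    Applies only when the preparation method involves added fat and the
    descriptor carries a positive absorption fraction; the absorbed grams are
    attributed to the fat specified by the participant.
    """
    if desc.fat_absorption_fraction <= 0:
        return None
    if entry.preparation_method not in FAT_USING_PREPARATIONS:
        return None
    if entry.fat_used_code is None:
        return None
    if entry.fat_used_code not in descriptors:
        raise IntakeError(
            f"{entry.food_code}: fat code {entry.fat_used_code!r} unresolvable"
        )
    return entry.fat_used_code, grams_as_consumed * desc.fat_absorption_fraction


def disaggregate_recipe(
    entry: FoodRecordEntry, recipe: Recipe
) -> list[tuple[str, float]]:
    """Split a consumed recipe fraction into ingredient grams.

    Each ingredient contributes fraction × its grams in the full recipe, so
    the output total is the fraction of the recipe total.
    """
    if entry.amount_unit is not AmountUnit.RECIPE_FRACTION:
        raise IntakeError(f"{entry.food_code}: entry is not a recipe fraction")
    fraction = entry.amount_value * entry.unit_count
    if not (0 < fraction <= 1):
        raise IntakeError(
            f"{entry.food_code}: recipe fraction {fraction} outside (0, 1]"
        )
    return [(code, fraction * grams) for code, grams in recipe.ingredients]


def _resolve_items(
    entries: Iterable[FoodRecordEntry],
    descriptors: Mapping[str, FoodDescriptor],
    recipes: Mapping[str, Recipe],
) -> list[tuple[str, float]]:
    """Flatten entries to (food_code, grams-as-consumed), including absorbed fat."""
    items: list[tuple[str, float]] = []
    missing: list[str] = []
    for entry in entries:
        if entry.identification_mode is IdentificationMode.SUPPLEMENT_ENTRY:
            continue  # supplements are tallied as a mode, never in totals
        if entry.amount_unit is AmountUnit.RECIPE_FRACTION:
            recipe = recipes.get(entry.food_code)
            if recipe is None:
                missing.append(entry.food_code)
                continue
            for code, grams in disaggregate_recipe(entry, recipe):
                if code not in descriptors:
                    missing.append(code)
                    continue
                items.append((code, grams))
            continue
        desc = descriptors.get(entry.food_code)
        if desc is None:
            missing.append(entry.food_code)
            continue
        grams = grams_consumed(entry, desc)
        items.append((entry.food_code, grams))
        absorbed = apply_fat_absorption(entry, desc, grams, descriptors)
        if absorbed is not None:
            items.append(absorbed)
    if missing:
        raise IntakeError(f"unresolvable food codes: {sorted(set(missing))}")
    return items


def daily_totals(
    entries: Sequence[FoodRecordEntry],
    descriptors: Mapping[str, FoodDescriptor],
    recipes: Optional[Mapping[str, Recipe]] = None,
    participant_id: Optional[str] = None,
    day_index: Optional[int] = None,
) -> DailyIntake:
    """Aggregate one participant-day of entries into a :class:`DailyIntake`.

    Every non-supplement entry maps to exactly one Wheel of Five group via
    its descriptor; nutrients accumulate as grams × per-gram composition.
    """
    if entries:
        pids = {e.participant_id for e in entries}
        days = {e.day_index for e in entries}
        if len(pids) > 1 or len(days) > 1:
            raise IntakeError(
                f"entries span multiple participant-days: {pids} x {days}"
            )
        participant_id = participant_id or next(iter(pids))
        day_index = day_index or next(iter(days))
    if participant_id is None or day_index is None:
        raise IntakeError("empty day requires explicit participant_id/day_index")

    daily = DailyIntake(participant_id=participant_id, day_index=day_index)
    items = _resolve_items(entries, descriptors, recipes or {})
    ungrouped: list[str] = []
    for code, grams in items:
        desc = descriptors[code]
        group = desc.food_group
        if group is None:
            ungrouped.append(code)
            continue
        daily.grams_by_group[group] = daily.grams_by_group.get(group, 0.0) + grams
        for nutrient, per_100g in desc.composition_per_100g.items():
            daily.nutrients[nutrient] = (
                daily.nutrients.get(nutrient, 0.0) + grams * per_100g / 100.0
            )
    if ungrouped:
        raise IntakeError(f"foods without a food group: {sorted(set(ungrouped))}")
    return daily
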