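"""Shared fixtures: a small hand-built food database and participants."""

from __future__ import annotations

import pytest

from dietvalid.records_io import (
    Education,
    FoodDescriptor,
    Gender,
    Participant,
)


@pytest.fixture
def descriptors() -> dict[str, FoodDescriptor]:
    """Hand-built foods exercising every conversion factor."""
    return {
        "apple": FoodDescriptor(
            food_code="apple",
            food_group="Fruit",
            edible_fraction=0.65,
            edible_units=frozenset({"gram", "piece"}),
            unit_weights_g={"piece": 120.0},
            composition_per_100g={"energy_kcal": 55.0, "carbohydrates_g": 12.0},
        ),
        "juice": FoodDescriptor(
            food_code="juice",
            food_group="Drinks",
            density_g_per_ml=1.03,
            composition_per_100g={"energy_kcal": 45.0, "carbohydrates_g": 10.0},
        ),
        "rice": FoodDescriptor(
            food_code="rice",
            food_group="Cereal products",
            yield_factor_by_prep={"boiled": 2.5},
            composition_per_100g={"energy_kcal": 130.0, "carbohydrates_g": 28.0},
        ),
        "schnitzel": FoodDescriptor(
            food_code="schnitzel",
            food_group="Meat",
            fat_absorption_fraction=0.05,
            composition_per_100g={"energy_kcal": 250.0, "protein_g": 20.0},
        ),
        "oil": FoodDescriptor(
            food_code="oil",
            food_group="Added fats",
            composition_per_100g={"energy_kcal": 884.0, "fat_g": 100.0},
        ),
        "bread": FoodDescriptor(
            food_code="bread",
            food_group="Bread",
            unit_weights_g={"slice": 35.0},
            composition_per_100g={"energy_kcal": 250.0, "carbohydrates_g": 46.0},
        ),
        "cola_brand": FoodDescriptor(
            food_code="cola_brand",
            food_group="Drinks",
            is_branded=True,
            generic_parent="juice",
            density_g_per_ml=1.0,
            composition_per_100g={"energy_kcal": 42.0, "carbohydrates_g": 10.5},
        ),
    }


@pytest.fixture
def participant() -> Participant:
    return Participant(
        participant_id="P0001",
        gender=Gender.MAN,
        age_years=30,
        height_m=1.80,
        weight_kg=80.0,
        education=Education.MIDDLE,
    )
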