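"""Energy-misreporting screening via estimated basal metabolic rate.

BMR is estimated from gender, age, weight and height with published linear
equations (the weight-and-height variant, MJ/day), shipped as a versioned TSV
asset so the coefficients are auditable and swappable.  A recording day is
implausible when the ratio of energy intake to BMR falls below 0.6 or above
3.0; such days are excluded before any paired comparison.

The measured physical activity level (PAL) is EI/BMR.  Relative energy
misreporting is (measured − expected PAL) / expected PAL, with the expected
PAL of a lightly active adult population defaulting to 1.59.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd

from .intake_engine import DailyIntake, KCAL_PER_MJ
from .records_io import Gender, Participant

__all__ = [
    "BmrCoefficientTable",
    "ScreenResult",
    "ReporterClass",
    "UnderreportingSummary",
    "henry_bmr",
    "screen_day",
    "screen_days",
    "underreporting_summary",
    "load_default_bmr_table",
    "EI_BMR_LOW",
    "EI_BMR_HIGH",
    "EXPECTED_PAL",
]

EI_BMR_LOW = 0.6
EI_BMR_HIGH = 3.0
EXPECTED_PAL = 1.59


@dataclass(frozen=True)
class BmrBand:
    gender: Gender
    age_min: int  # inclusive
    age_max: int  # exclusive
    intercept_mj: float
    coef_weight: float  # MJ/day per kg
    coef_height: float  # MJ/day per m


@dataclass(frozen=True)
class BmrCoefficientTable:
    """Age-and-gender banded linear BMR equations (MJ/day output)."""

    bands: tuple[BmrBand, ...]

    def __post_init__(self) -> None:
        # bands must partition the adult age range without overlap, per gender
        for gender in Gender:
            rows = sorted(
                (b for b in self.bands if b.gender is gender),
                key=lambda b: b.age_min,
            )
            for a, b in zip(rows, rows[1:]):
                if a.age_max != b.age_min:
                    raise ValueError(
                        f"BMR bands for {gender.value} do not partition: "
                        f"{a.age_max} != {b.age_min}"
                    )

    def band_for(self, gender: Gender, age_years: float) -> BmrBand:
        for band in self.bands:
            if band.gender is gender and band.age_min <= age_years < band.age_max:
                return band
        raise ValueError(
            f"age {age_years} outside covered BMR bands for {gender.value}"
        )


def load_default_bmr_table() -> BmrCoefficientTable:
    path = resources.files("dietvalid.data") / "henry_bmr_coefficients.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    bands = tuple(
        BmrBand(
            gender=Gender(row.gender),
            age_min=int(row.age_min),
            age_max=int(row.age_max),
            intercept_mj=float(row.intercept_mj),
            coef_weight=float(row.coef_weight_mj_per_kg),
            coef_height=float(row.coef_height_mj_per_m),
        )
        for row in df.itertuples(index=False)
    )
    return BmrCoefficientTable(bands=bands)


_DEFAULT_TABLE: Optional[BmrCoefficientTable] = None


def _default_table() -> BmrCoefficientTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_default_bmr_table()
    return _DEFAULT_TABLE


def henry_bmr(
    gender: Gender,
    age_years: float,
    weight_kg: float,
    height_m: float,
    table: Optional[BmrCoefficientTable] = None,
) -> float:
    """Estimated BMR in kcal/day from the banded weight-and-height equations."""
    if weight_kg <= 0 or height_m <= 0:
        raise ValueError("weight and height must be positive")
    band = (table or _default_table()).band_for(gender, age_years)
    mj = (
        band.intercept_mj
        + band.coef_weight * weight_kg
        + band.coef_height * height_m
    )
    return mj * KCAL_PER_MJ


class ReporterClass(str, enum.Enum):
    UNDER = "under"
    PLAUSIBLE = "plausible"
    OVER = "over"


@dataclass(frozen=True)
class ScreenResult:
    participant_id: str
    day_index: int
    energy_kcal: float
    bmr_kcal: float
    ei_bmr_low: float = EI_BMR_LOW
    ei_bmr_high: float = EI_BMR_HIGH

    @property
    def ei_bmr_ratio(self) -> float:
        return self.energy_kcal / self.bmr_kcal

    @property
    def plausible(self) -> bool:
        return self.ei_bmr_low <= self.ei_bmr_ratio <= self.ei_bmr_high

    @property
    def reporter_class(self) -> ReporterClass:
        r = self.ei_bmr_ratio
        if r < self.ei_bmr_low:
            return ReporterClass.UNDER
        if r > self.ei_bmr_high:
            return ReporterClass.OVER
        return ReporterClass.PLAUSIBLE


def screen_day(
    daily: DailyIntake,
    participant: Participant,
    table: Optional[BmrCoefficientTable] = None,
    ei_bmr_low: float = EI_BMR_LOW,
    ei_bmr_high: float = EI_BMR_HIGH,
) -> ScreenResult:
    """Screen one recording day for implausible energy intake.

    A day is plausible iff low <= EI/BMR <= high (defaults 0.6 and 3.0; the
    exclusion rule drops days strictly below 0.6 or strictly above 3.0, so
    boundaries are kept).
    """
    bmr = henry_bmr(
        participant.gender,
        participant.age_years,
        participant.weight_kg,
        participant.height_m,
        table,
    )
    return ScreenResult(
        participant_id=daily.participant_id,
        day_index=daily.day_index,
        energy_kcal=daily.energy_kcal,
        bmr_kcal=bmr,
        ei_bmr_low=ei_bmr_low,
        ei_bmr_high=ei_bmr_high,
    )


def screen_days(
    days: Iterable[DailyIntake],
    participants: dict[str, Participant],
    table: Optional[BmrCoefficientTable] = None,
    ei_bmr_low: float = EI_BMR_LOW,
    ei_bmr_high: float = EI_BMR_HIGH,
) -> list[ScreenResult]:
    return [
        screen_day(d, participants[d.participant_id], table, ei_bmr_low, ei_bmr_high)
        for d in days
    ]


@dataclass(frozen=True)
class UnderreportingSummary:
    """Cohort-level energy misreporting relative to an expected PAL."""

    n: int
    mean_pal: float
    expected_pal: float
    mean_relative_misreporting: float  # (mean PAL - expected) / expected
    n_under: int
    n_over: int
    classes: dict[str, str]  # participant -> under/plausible/over

    @property
    def mean_relative_misreporting_pct(self) -> float:
        return 100.0 * self.mean_relative_misreporting


def underreporting_summary(
    screens: Sequence[ScreenResult],
    expected_pal: float = EXPECTED_PAL,
    under_cutoff: float = 1.10,
    over_cutoff: float = 2.0,
) -> UnderreportingSummary:
    """Mean relative misreporting and per-person reporter classes.

    The measured PAL per person is EI/BMR; relative misreporting is
    (measured − expected) / expected.  Per-person classes use configurable
    measured-PAL cutoffs (defaults: under < 1.10, over > 2.0).
    """
    if not screens:
        raise ValueError("underreporting_summary requires >= 1 screen result")
    pals = {s.participant_id: s.ei_bmr_ratio for s in screens}
    mean_pal = sum(pals.values()) / len(pals)
    classes = {}
    for pid, pal in pals.items():
        if pal < under_cutoff:
            classes[pid] = "under"
        elif pal > over_cutoff:
            classes[pid] = "over"
        else:
            classes[pid] = "plausible"
    return UnderreportingSummary(
        n=len(pals),
        mean_pal=mean_pal,
        expected_pal=expected_pal,
        mean_relative_misreporting=(mean_pal - expected_pal) / expected_pal,
        n_under=sum(1 for c in classes.values() if c == "under"),
        n_over=sum(1 for c in classes.values() if c == "over"),
        classes=classes,
    )
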