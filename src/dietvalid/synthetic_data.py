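"""Synthetic paired dietary studies with known ground truth.

The generator emulates the structure of a relative-validity study in which
each participant records one day with a smartphone food record (method A)
while the same day is captured by an interviewer-administered 24-hour recall
(method B, the reference):

* demographics follow the published cohort mix (gender, 3 age bands,
  3 education classes, 4 BMI classes);
* daily food-group amounts under the reference method are zero-inflated
  lognormal — a consumption probability per group and a lognormal positive
  part (intakes are positive and right-skewed);
* the record method sees the reference amount times a per-group bias ratio
  and multiplicative lognormal noise, with an independent per-group omission
  probability (forgotten condiments and sauces);
* each participant's physical activity level (PAL = energy intake / BMR) is
  lognormal with median 1.59; a configured fraction of participants are
  extreme energy reporters with PAL outside the 0.6–3.0 plausibility window.
  Record amounts are rescaled per participant so the record-day energy equals
  PAL × BMR exactly, making the energy screen's behaviour fully known.

Per-group defaults are anchored to the published consumer shares and
consumers-only medians of the reference method, with the bias ratio taken as
the published record/recall consumer-median ratio.  All outputs are pure
functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .plausibility import henry_bmr
from .records_io import (
    AmountUnit,
    DialectConfig,
    Education,
    FoodDescriptor,
    FoodRecordEntry,
    Gender,
    IdentificationMode,
    Occasion,
    Participant,
    ReportedState,
    WHEEL_OF_FIVE_GROUPS,
    write_composition_table,
    write_food_records,
    write_group_map,
    write_roster,
)

__all__ = [
    "GroupSpec",
    "SyntheticConfig",
    "SyntheticStudy",
    "default_config",
    "recovery_config",
    "generate_cohort",
    "generate_food_database",
    "generate_paired_study",
    "ground_truth",
]


@dataclass(frozen=True)
class GroupSpec:
    """Generative model of one food group.

    ``p_consume`` and ``median_g`` describe the reference method's
    zero-inflated lognormal (consumption probability per day; consumers-only
    median grams).  ``bias`` multiplies the reference amount for the record
    method, ``noise_sigma`` is the lognormal dispersion of the record noise,
    and ``p_omit`` is the probability that a consumed group is missing from
    the record entirely.
    """

    name: str
    p_consume: float
    median_g: float
    sigma_log: float = 0.8
    bias: float = 1.0
    noise_sigma: float = 0.6
    p_omit: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.p_consume <= 1 and 0 <= self.p_omit <= 1):
            raise ValueError(f"{self.name}: probabilities must lie in [0, 1]")
        if self.bias <= 0:
            raise ValueError(f"{self.name}: bias ratio must be positive")
        if self.median_g <= 0:
            raise ValueError(f"{self.name}: median must be positive")


# published consumer shares / consumers-only medians (reference method) and
# record/recall consumer-median ratios; omission = consumer-share deficit
_DEFAULT_GROUP_ROWS: tuple[tuple[str, int, float, int, float], ...] = (
    # (group, consumers_record, median_record, consumers_recall, median_recall)
    ("Vegetables", 175, 146, 181, 147),
    ("Fruit", 134, 156, 148, 165),
    ("Added fats", 173, 15, 186, 20),
    ("Fish", 25, 90, 26, 115),
    ("Legumes", 5, 111, 10, 79),
    ("Meat", 178, 86, 179, 85),
    ("Eggs", 52, 50, 61, 50),
    ("Nuts", 66, 32, 70, 31),
    ("Milk and milk products", 165, 265, 173, 302),
    ("Cheese", 138, 36, 145, 45),
    ("Bread", 194, 136, 198, 140),
    ("Cereal products", 113, 70, 124, 98),
    ("Potatoes", 87, 150, 90, 142),
    ("Drinks", 206, 1848, 211, 1963),
    ("Sandwich spreads", 85, 26, 89, 20),
    ("Soups", 33, 188, 28, 50),
    ("Snacks", 173, 72, 172, 78),
    ("Sauces", 116, 24, 143, 45),
    ("Other", 126, 5, 59, 12),
)

_COHORT_N = 211  # reference cohort size behind the default proportions

#: typical energy densities per group, kcal per 100 g as consumed
_ENERGY_DENSITY_KCAL_100G: dict[str, float] = {
    "Vegetables": 30,
    "Fruit": 55,
    "Added fats": 720,
    "Fish": 150,
    "Legumes": 90,
    "Meat": 200,
    "Eggs": 150,
    "Nuts": 600,
    "Milk and milk products": 60,
    "Cheese": 350,
    "Bread": 250,
    "Cereal products": 130,
    "Potatoes": 85,
    "Drinks": 20,
    "Sandwich spreads": 250,
    "Soups": 40,
    "Snacks": 400,
    "Sauces": 120,
    "Other": 300,
}

#: crude macronutrient profiles (g per 100 g) per group: protein, fat, carbs
_MACROS_PER_100G: dict[str, tuple[float, float, float]] = {
    "Vegetables": (1.5, 0.3, 4.0),
    "Fruit": (0.6, 0.2, 12.0),
    "Added fats": (0.2, 80.0, 0.5),
    "Fish": (20.0, 8.0, 0.0),
    "Legumes": (7.0, 0.5, 14.0),
    "Meat": (22.0, 12.0, 0.5),
    "Eggs": (12.5, 10.0, 0.5),
    "Nuts": (20.0, 52.0, 10.0),
    "Milk and milk products": (3.5, 3.0, 4.5),
    "Cheese": (24.0, 28.0, 1.0),
    "Bread": (9.0, 2.0, 46.0),
    "Cereal products": (4.0, 1.5, 25.0),
    "Potatoes": (2.0, 0.2, 18.0),
    "Drinks": (0.2, 0.1, 4.5),
    "Sandwich spreads": (6.0, 12.0, 30.0),
    "Soups": (1.5, 1.5, 4.0),
    "Snacks": (6.0, 20.0, 45.0),
    "Sauces": (1.5, 8.0, 10.0),
    "Other": (5.0, 12.0, 40.0),
}

#: identification-mode mix of record entries (non-supplement), from the
#: published tallies 211/175/169/114/16/147 of 832
_MODE_WEIGHTS: tuple[tuple[IdentificationMode, float], ...] = (
    (IdentificationMode.GENERIC_SEARCH, 211 / 832),
    (IdentificationMode.PREVIOUSLY_SELECTED, 175 / 832),
    (IdentificationMode.BRANDED_SEARCH, 169 / 832),
    (IdentificationMode.BARCODE_SCAN, 114 / 832),
    (IdentificationMode.RECIPE, 16 / 832),
    (IdentificationMode.ASSOCIATED_ITEM, 147 / 832),
)

_GROUP_OCCASIONS: tuple[Occasion, ...] = (
    Occasion.BREAKFAST,
    Occasion.MIDDAY_MEAL,
    Occasion.EVENING_MEAL,
    Occasion.IN_BETWEEN,
)
_OCCASION_TIMES = {
    Occasion.BREAKFAST: "08:00",
    Occasion.MIDDAY_MEAL: "12:30",
    Occasion.EVENING_MEAL: "18:00",
    Occasion.IN_BETWEEN: "15:00",
    Occasion.SUPPLEMENT: None,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Full specification of a synthetic paired study."""

    n_participants: int = _COHORT_N
    seed: int = 0
    # demographic mixes (published cohort proportions)
    gender_weights: tuple[float, float] = (104 / 211, 107 / 211)  # man, woman
    age_band_weights: tuple[float, float, float] = (
        76 / 211,
        77 / 211,
        58 / 211,
    )  # 18-39, 40-59, 60-79
    education_weights: tuple[float, float, float] = (
        37 / 211,
        81 / 211,
        93 / 211,
    )  # low, middle, high
    bmi_class_weights: tuple[float, float, float, float] = (
        1 / 211,
        81 / 211,
        73 / 211,
        56 / 211,
    )  # <18.5, 18.5-25, 25-30, >=30
    groups: tuple[GroupSpec, ...] = ()
    pal_median: float = 1.59
    pal_sigma: float = 0.20
    extreme_fraction: float = 16 / 227
    p_supplement: float = 0.25
    pool_size: Optional[int] = None  # default: n_participants
    guarantee_matches: bool = False
    day_index: int = 1


def default_config(n_participants: int = _COHORT_N, seed: int = 0) -> SyntheticConfig:
    """Study-condition defaults: the published cohort mix and per-group
    consumption model anchored to the published consumer tables."""
    groups = []
    for name, cons_a, med_a, cons_b, med_b in _DEFAULT_GROUP_ROWS:
        groups.append(
            GroupSpec(
                name=name,
                p_consume=cons_b / _COHORT_N,
                median_g=float(med_b),
                sigma_log=0.8,
                bias=med_a / med_b,
                noise_sigma=0.6,
                p_omit=max(0.0, 1.0 - cons_a / cons_b),
            )
        )
    return SyntheticConfig(
        n_participants=n_participants, seed=seed, groups=tuple(groups)
    )


def recovery_config(n_participants: int = 1000, seed: int = 0) -> SyntheticConfig:
    """A parameter-recovery configuration: frequently consumed groups with
    injected bias ratios spanning 0.6–1.2, moderate dispersion and no
    omission, so median-ratio and rank-correlation estimators are
    identifiable at the configured sample size."""
    spec = dict(sigma_log=0.6, noise_sigma=0.3, p_omit=0.0)
    groups = (
        GroupSpec("Vegetables", 0.95, 150.0, bias=0.6, **spec),
        GroupSpec("Fruit", 0.85, 160.0, bias=0.8, **spec),
        GroupSpec("Meat", 0.90, 90.0, bias=1.0, **spec),
        GroupSpec("Bread", 0.95, 140.0, bias=1.2, **spec),
        GroupSpec("Milk and milk products", 0.80, 300.0, bias=0.9, **spec),
        GroupSpec("Drinks", 1.0, 1900.0, bias=0.7, **spec),
    )
    return SyntheticConfig(
        n_participants=n_participants, seed=seed, groups=tuple(groups)
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _allocate(n: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of n units over classes (matches the
    requested proportions within rounding)."""
    total = sum(weights)
    if total <= 0:
        raise ValueError("infeasible proportions")
    quotas = [n * w / total for w in weights]
    counts = [int(q) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(
        range(len(weights)), key=lambda i: quotas[i] - counts[i], reverse=True
    )
    for i in order[:remainder]:
        counts[i] += 1
    return counts

_AGE_BANDS = ((18, 39), (40, 59), (60, 79))
_BMI_RANGES = ((17.5, 18.5), (18.5, 25.0), (25.0, 30.0), (30.0, 40.0))
_HEIGHT_BY_GENDER = {Gender.MAN: (1.81, 0.07), Gender.WOMAN: (1.67, 0.06)}


def _draw_participants(
    config: SyntheticConfig, rng: np.random.Generator, n: int, prefix: str
) -> list[Participant]:
    genders = [Gender.MAN] * _allocate(n, config.gender_weights)[0]
    genders += [Gender.WOMAN] * (n - len(genders))
    age_counts = _allocate(n, config.age_band_weights)
    ages: list[int] = []
    for (lo, hi), count in zip(_AGE_BANDS, age_counts):
        ages.extend(int(a) for a in rng.integers(lo, hi + 1, size=count))
    edu_counts = _allocate(n, config.education_weights)
    educations: list[Education] = []
    for edu, count in zip(Education, edu_counts):
        educations.extend([edu] * count)
    bmi_counts = _allocate(n, config.bmi_class_weights)
    bmis: list[float] = []
    for (lo, hi), count in zip(_BMI_RANGES, bmi_counts):
        bmis.extend(rng.uniform(lo, hi, size=count))

    # shuffle each attribute independently so classes are not correlated
    for seq in (ages, educations, bmis):
        rng.shuffle(seq)  # type: ignore[arg-type]

    participants = []
    for i in range(n):
        gender = genders[i]
        mu, sd = _HEIGHT_BY_GENDER[gender]
        height = float(np.clip(rng.normal(mu, sd), 1.45, 2.10))
        weight = bmis[i] * height**2
        participants.append(
            Participant(
                participant_id=f"{prefix}{i + 1:04d}",
                gender=gender,
                age_years=ages[i],
                height_m=round(height, 3),
                weight_kg=round(weight, 1),
                education=educations[i],
            )
        )
    return participants


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[Participant], list[Participant]]:
    """Generate the case roster and the external comparator pool.

    With ``guarantee_matches`` every case has at least one full-key pool
    entry (same gender, education, age band and weight band, nearby height).
    """
    rng = np.random.default_rng(config.seed)
    cases = _draw_participants(config, rng, config.n_participants, "P")
    pool_n = config.pool_size or config.n_participants
    pool = _draw_participants(config, rng, pool_n, "Q")
    if config.guarantee_matches:
        guaranteed = []
        for i, case in enumerate(cases):
            # clone the matching key; jitter height within the band
            guaranteed.append(
                Participant(
                    participant_id=f"Q{pool_n + i + 1:04d}",
                    gender=case.gender,
                    age_years=case.age_years,
                    height_m=round(
                        float(np.clip(case.height_m + rng.normal(0, 0.01), 1.45, 2.10)),
                        3,
                    ),
                    weight_kg=case.weight_kg,
                    education=case.education,
                )
            )
        pool = pool + guaranteed
    return cases, pool


# ---------------------------------------------------------------------------
# Food database fixture
# ---------------------------------------------------------------------------

def generate_food_database(
    config: SyntheticConfig,
) -> tuple[dict[str, FoodDescriptor], dict[str, str]]:
    """One generic and one branded food per configured group, with plausible
    energy densities and macronutrient profiles."""
    descriptors: dict[str, FoodDescriptor] = {}
    group_map: dict[str, str] = {}
    for idx, spec in enumerate(config.groups):
        energy = _ENERGY_DENSITY_KCAL_100G.get(spec.name, 150.0)
        protein, fat, carbs = _MACROS_PER_100G.get(spec.name, (5.0, 5.0, 20.0))
        comp = {
            "energy_kcal": energy,
            "protein_g": protein,
            "fat_g": fat,
            "carbohydrates_g": carbs,
        }
        generic_code = f"F{idx:02d}"
        branded_code = f"B{idx:02d}"
        density = 1.03 if spec.name == "Drinks" else None
        descriptors[generic_code] = FoodDescriptor(
            food_code=generic_code,
            food_group=spec.name,
            density_g_per_ml=density,
            composition_per_100g=comp,
        )
        descriptors[branded_code] = FoodDescriptor(
            food_code=branded_code,
            food_group=spec.name,
            is_branded=True,
            generic_parent=generic_code,
            density_g_per_ml=density,
            composition_per_100g=comp,
        )
        group_map[generic_code] = spec.name
        group_map[branded_code] = spec.name
    return descriptors, group_map


# ---------------------------------------------------------------------------
# Paired study generation
# ---------------------------------------------------------------------------

def _draw_amount_matrices(
    config: SyntheticConfig,
    rng: np.random.Generator,
    participants: Sequence[Participant],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Scaled daily group amounts for both methods.

    Returns (amounts_record, amounts_recall, pal, extreme_mask); matrices are
    n_participants × n_groups, grams as consumed.  Record-method day energy
    equals pal × BMR exactly after scaling.
    """
    n = len(participants)
    n_groups = len(config.groups)
    b = np.zeros((n, n_groups))
    a = np.zeros((n, n_groups))
    for j, spec in enumerate(config.groups):
        consumes = rng.random(n) < spec.p_consume
        positive = rng.lognormal(np.log(spec.median_g), spec.sigma_log, size=n)
        b[:, j] = np.where(consumes, positive, 0.0)
        omitted = rng.random(n) < spec.p_omit
        noise = rng.lognormal(0.0, spec.noise_sigma, size=n)
        a[:, j] = np.where(omitted, 0.0, b[:, j] * spec.bias * noise)

    pal = rng.lognormal(np.log(config.pal_median), config.pal_sigma, size=n)
    n_extreme = int(round(config.extreme_fraction * n))
    extreme_mask = np.zeros(n, dtype=bool)
    if n_extreme:
        idx = rng.choice(n, size=n_extreme, replace=False)
        extreme_mask[idx] = True
        # mostly implausibly low reporters, occasionally implausibly high
        low = rng.random(n_extreme) < 0.8
        extreme_pal = np.where(
            low, rng.uniform(0.25, 0.50, n_extreme), rng.uniform(3.3, 4.0, n_extreme)
        )
        pal[idx] = extreme_pal

    energy_density = np.array(
        [_ENERGY_DENSITY_KCAL_100G.get(s.name, 150.0) for s in config.groups]
    )
    energy_a_raw = a @ energy_density / 100.0
    bmr = np.array(
        [
            henry_bmr(p.gender, p.age_years, p.weight_kg, p.height_m)
            for p in participants
        ]
    )
    target = pal * bmr
    scale = np.where(energy_a_raw > 0, target / np.maximum(energy_a_raw, 1e-12), 1.0)
    return a * scale[:, None], b * scale[:, None], pal, extreme_mask


def _amounts_to_entries(
    config: SyntheticConfig,
    rng: np.random.Generator,
    participants: Sequence[Participant],
    amounts: np.ndarray,
    method: str,
    descriptors: dict[str, FoodDescriptor],
) -> list[FoodRecordEntry]:
    modes, weights = zip(*_MODE_WEIGHTS)
    entries: list[FoodRecordEntry] = []
    for i, participant in enumerate(participants):
        for j, spec in enumerate(config.groups):
            grams = amounts[i, j]
            if grams <= 0:
                continue
            occasion = _GROUP_OCCASIONS[j % len(_GROUP_OCCASIONS)]
            if method == "record":
                mode = modes[int(rng.choice(len(modes), p=weights))]
            else:
                mode = IdentificationMode.GENERIC_SEARCH
            branded = mode in (
                IdentificationMode.BRANDED_SEARCH,
                IdentificationMode.BARCODE_SCAN,
            )
            code = (f"B{j:02d}" if branded else f"F{j:02d}")
            desc = descriptors[code]
            if desc.density_g_per_ml is not None:
                unit = AmountUnit.MILLILITER
                value = grams / desc.density_g_per_ml
            else:
                unit = AmountUnit.GRAM
                value = grams
            entries.append(
                FoodRecordEntry(
                    participant_id=participant.participant_id,
                    day_index=config.day_index,
                    occasion=occasion,
                    clock_time=_OCCASION_TIMES[occasion],
                    place="home",
                    food_code=code,
                    identification_mode=mode,
                    amount_value=float(value),
                    amount_unit=unit,
                    unit_count=1.0,
                    reported_state=ReportedState.AS_CONSUMED,
                )
            )
        if method == "record" and rng.random() < config.p_supplement:
            entries.append(
                FoodRecordEntry(
                    participant_id=participant.participant_id,
                    day_index=config.day_index,
                    occasion=Occasion.SUPPLEMENT,
                    food_code="SUPP01",
                    identification_mode=IdentificationMode.SUPPLEMENT_ENTRY,
                    amount_value=1.0,
                    amount_unit=AmountUnit.GRAM,
                )
            )
    return entries


@dataclass
class SyntheticStudy:
    """All artifacts of one generated study, plus its generating truth."""

    config: SyntheticConfig
    participants: list[Participant]
    pool: list[Participant]
    descriptors: dict[str, FoodDescriptor]
    group_map: dict[str, str]
    entries_record: list[FoodRecordEntry]
    entries_recall: list[FoodRecordEntry]
    pal: np.ndarray
    extreme_mask: np.ndarray
    paths: dict[str, Path] = field(default_factory=dict)

    @property
    def extreme_ids(self) -> set[str]:
        return {
            p.participant_id
            for p, is_extreme in zip(self.participants, self.extreme_mask)
            if is_extreme
        }


def generate_paired_study(
    config: SyntheticConfig, outdir: Optional[str | Path] = None
) -> SyntheticStudy:
    """Generate a full paired study; optionally write it in the file formats
    the I/O layer reads (records, composition table, group map, rosters)."""
    if not config.groups:
        raise ValueError("config.groups is empty; use default_config()")
    rng = np.random.default_rng(config.seed)
    cases = _draw_participants(config, rng, config.n_participants, "P")
    pool = _draw_participants(
        config, rng, config.pool_size or config.n_participants, "Q"
    )
    descriptors, group_map = generate_food_database(config)
    amounts_a, amounts_b, pal, extreme = _draw_amount_matrices(config, rng, cases)
    entries_a = _amounts_to_entries(config, rng, cases, amounts_a, "record", descriptors)
    entries_b = _amounts_to_entries(config, rng, cases, amounts_b, "recall", descriptors)

    study = SyntheticStudy(
        config=config,
        participants=cases,
        pool=pool,
        descriptors=descriptors,
        group_map=group_map,
        entries_record=entries_a,
        entries_recall=entries_b,
        pal=pal,
        extreme_mask=extreme,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "records_record": outdir / "records_record.csv",
            "records_recall": outdir / "records_recall.csv",
            "composition": outdir / "composition.tsv",
            "group_map": outdir / "group_map.tsv",
            "roster": outdir / "roster.csv",
            "pool": outdir / "pool.csv",
        }
        write_food_records(entries_a, paths["records_record"])
        write_food_records(entries_b, paths["records_recall"])
        write_composition_table(descriptors, paths["composition"])
        write_group_map(group_map, paths["group_map"])
        write_roster(cases, paths["roster"])
        write_roster(pool, paths["pool"])
        study.paths = paths
    return study


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def ground_truth(
    config: SyntheticConfig, mc_n: int = 100_000
) -> dict[str, dict[str, float]]:
    """Per-group generating truth for recovery tests.

    Closed forms where available (bias ratio, consumer probabilities,
    consumers-only medians: the lognormal median is exp(mu), and the record
    noise has median 1); the all-participant Spearman correlation — which has
    no convenient closed form under zero inflation, omission and the common
    per-participant energy scaling — is computed by Monte Carlo at ``mc_n``
    simulated participants from the same generative model.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 987654321)))
    cfg_mc = replace(config, n_participants=mc_n)
    participants = _draw_participants(cfg_mc, rng, mc_n, "M")
    a, b, _, _ = _draw_amount_matrices(cfg_mc, rng, participants)

    truth: dict[str, dict[str, float]] = {}
    for j, spec in enumerate(config.groups):
        col_a, col_b = a[:, j], b[:, j]
        rx = _rank(col_a)
        ry = _rank(col_b)
        rho = float(np.corrcoef(rx, ry)[0, 1])
        truth[spec.name] = {
            "bias": spec.bias,
            "p_consume_recall": spec.p_consume,
            "p_consume_record": spec.p_consume * (1.0 - spec.p_omit),
            "median_consumers_recall": spec.median_g,
            "median_consumers_record": spec.median_g * spec.bias,
            "spearman_rho": rho,
        }
    return truth


def _rank(x: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(x)
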