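"""One-to-one comparator selection on intake-associated characteristics.

Each case is matched to one participant of an external pool on gender, age
class (5-year bands), weight class (10-kg bands) and educational level
(3 classes).  When no full-key match exists, criteria are relaxed stepwise:
first education is dropped, then the age class.  Among eligible comparators
the one with the same or the closest height is chosen; ties break to the
smallest comparator id.  Assignment is greedy without replacement in roster
order — the simplest deterministic 1:1 scheme; a globally optimal assignment
(e.g. Hungarian) is out of scope.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from .records_io import Education, Gender, Participant

__all__ = [
    "BandConfig",
    "MatchKey",
    "MatchResult",
    "RelaxationLevel",
    "build_match_key",
    "match_cohort",
]


@dataclass(frozen=True)
class BandConfig:
    age_band_years: int = 5
    weight_band_kg: int = 10


@dataclass(frozen=True)
class MatchKey:
    """Banded matching key; bands are lower-inclusive half-open intervals
    anchored at multiples of the band width."""

    gender: Gender
    age_class: int  # lower bound of the age band
    weight_class: int  # lower bound of the weight band
    education: Education


class RelaxationLevel(str, enum.Enum):
    FULL = "full"
    EDUCATION_RELAXED = "education_relaxed"
    AGE_RELAXED = "age_relaxed"
    UNMATCHED = "unmatched"


@dataclass(frozen=True)
class MatchResult:
    case_id: str
    control_id: Optional[str]
    relaxation_level: RelaxationLevel
    height_gap_m: Optional[float]


def build_match_key(
    participant: Participant, bands: BandConfig = BandConfig()
) -> MatchKey:
    """Deterministic banding: age in [k*w, (k+1)*w), weight likewise."""
    return MatchKey(
        gender=participant.gender,
        age_class=bands.age_band_years
        * math.floor(participant.age_years / bands.age_band_years),
        weight_class=bands.weight_band_kg
        * math.floor(participant.weight_kg / bands.weight_band_kg),
        education=participant.education,
    )


def _eligible(
    case_key: MatchKey, control_key: MatchKey, level: RelaxationLevel
) -> bool:
    if case_key.gender is not control_key.gender:
        return False
    if case_key.weight_class != control_key.weight_class:
        return False
    if level is RelaxationLevel.FULL:
        return (
            case_key.age_class == control_key.age_class
            and case_key.education is control_key.education
        )
    if level is RelaxationLevel.EDUCATION_RELAXED:
        return case_key.age_class == control_key.age_class
    if level is RelaxationLevel.AGE_RELAXED:
        return True
    raise ValueError(level)


def match_cohort(
    cases: Sequence[Participant],
    pool: Sequence[Participant],
    bands: BandConfig = BandConfig(),
) -> list[MatchResult]:
    """Greedy 1:1 matching without replacement, cases in roster order.

    Per case the full key is tried first, then education is dropped, then the
    age class; gender and weight class are never relaxed.  Among eligible
    comparators the minimal absolute height difference wins, ties broken by
    smallest comparator id.  Unmatched cases are recorded, never fabricated.
    """
    case_ids = {c.participant_id for c in cases}
    overlap = case_ids & {p.participant_id for p in pool}
    if overlap:
        raise ValueError(f"pool overlaps cases: {sorted(overlap)}")
    if not pool:
        warnings.warn("empty comparator pool: all cases unmatched", stacklevel=2)

    pool_keys = {p.participant_id: build_match_key(p, bands) for p in pool}
    available: dict[str, Participant] = {p.participant_id: p for p in pool}

    results: list[MatchResult] = []
    for case in cases:
        case_key = build_match_key(case, bands)
        chosen: Optional[Participant] = None
        chosen_level = RelaxationLevel.UNMATCHED
        for level in (
            RelaxationLevel.FULL,
            RelaxationLevel.EDUCATION_RELAXED,
            RelaxationLevel.AGE_RELAXED,
        ):
            candidates = [
                p
                for pid, p in available.items()
                if _eligible(case_key, pool_keys[pid], level)
            ]
            if candidates:
                chosen = min(
                    candidates,
                    key=lambda p: (
                        abs(p.height_m - case.height_m),
                        p.participant_id,
                    ),
                )
                chosen_level = level
                break
        if chosen is None:
            results.append(
                MatchResult(
                    case_id=case.participant_id,
                    control_id=None,
                    relaxation_level=RelaxationLevel.UNMATCHED,
                    height_gap_m=None,
                )
            )
        else:
            del available[chosen.participant_id]
            results.append(
                MatchResult(
                    case_id=case.participant_id,
                    control_id=chosen.participant_id,
                    relaxation_level=chosen_level,
                    height_gap_m=abs(chosen.height_m - case.height_m),
                )
            )
    return results
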