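"""Score reported intakes (g/day) as food-group servings/day and compare
them with recommendation profiles.

The summary table gives servings per 100 g for each FFQ item, so a
person's daily servings of each food group are the linear combination

    servings/day = sum over items of  g/day x (servings per 100 g) / 100.

Discretionary servings accumulate the same way but are reported
independently of the five food groups (a mixed dish such as a hamburger
contributes to both).  Adherence uses the guidelines' directionality:
food-group targets are adequacy floors (consumed >= recommended), the
discretionary limit is a ceiling (consumed <= limit).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import FormatError, ValidationError
from .food_model import (
    ADGATRow,
    ADGATTable,
    FoodGroupVector,
    GROUP_FIELDS,
    IntakeRecord,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DailyServings:
    """One person's food-group and discretionary servings per day."""

    person_id: str
    groups: FoodGroupVector
    discretionary_servings_per_day: float

    def __post_init__(self):
        d = self.discretionary_servings_per_day
        if not math.isfinite(d) or d < 0:
            raise ValidationError(
                f"person '{self.person_id}': discretionary servings/day must "
                f"be a non-negative finite number, got {d!r}"
            )


@dataclass(frozen=True)
class RecommendationProfile:
    """Recommended servings/day for one age-sex stratum.

    The recommendation numbers are user-supplied configuration (they vary
    by age and sex and are published separately from the database).
    """

    profile_id: str
    recommended: FoodGroupVector
    discretionary_max: float | None = None

    def __post_init__(self):
        for name, v in zip(GROUP_FIELDS, self.recommended.as_tuple()):
            if v <= 0:
                raise ValidationError(
                    f"profile '{self.profile_id}': recommended '{name}' must "
                    f"be > 0, got {v!r}"
                )
        if self.discretionary_max is not None and self.discretionary_max < 0:
            raise ValidationError(
                f"profile '{self.profile_id}': discretionary_max must be "
                f">= 0, got {self.discretionary_max!r}"
            )


@dataclass(frozen=True)
class GroupAdherence:
    group: str
    consumed: float
    recommended: float
    ratio: float
    met: bool


@dataclass(frozen=True)
class AdherenceReport:
    person_id: str
    profile_id: str
    groups: tuple[GroupAdherence, ...]
    discretionary_consumed: float
    discretionary_limit: float | None
    discretionary_within_limit: bool | None


def compute_item_servings(
    intake: IntakeRecord, row: ADGATRow
) -> tuple[FoodGroupVector, float]:
    """Per-item contribution: g/day scaled by the row's servings/100 g."""
    if intake.item_name != row.item_name:
        raise ValidationError(
            f"intake item '{intake.item_name}' does not match row "
            f"'{row.item_name}'"
        )
    factor = intake.grams_per_day / 100.0
    return row.groups.scale(factor), row.discretionary_servings_per_100g * factor


def aggregate_daily_servings(
    intakes: Sequence[IntakeRecord],
    table: ADGATTable,
    person_id: str = "",
) -> DailyServings:
    """Total servings/day for one person: sum of per-item contributions.

    Unknown item names raise; duplicate items for the same person are
    summed (with a logged warning), treating them as split reports.
    """
    unknown = sorted({r.item_name for r in intakes if r.item_name not in table})
    if unknown:
        raise ValidationError(
            f"intake refers to item(s) absent from the summary table: "
            f"{', '.join(unknown)}"
        )
    dupes = [name for name, k in Counter(r.item_name for r in intakes).items() if k > 1]
    if dupes:
        logger.warning(
            "person '%s': duplicate intake records summed for: %s",
            person_id,
            ", ".join(sorted(dupes)),
        )
    total = FoodGroupVector.zero()
    disc = 0.0
    for rec in intakes:
        contrib, d = compute_item_servings(rec, table[rec.item_name])
        total = total + contrib
        disc += d
    return DailyServings(
        person_id=person_id, groups=total, discretionary_servings_per_day=disc
    )


def adherence_report(
    servings: DailyServings, profile: RecommendationProfile
) -> AdherenceReport:
    """Compare one person's servings/day with a recommendation profile."""
    groups = []
    for name, consumed, recommended in zip(
        GROUP_FIELDS, servings.groups.as_tuple(), profile.recommended.as_tuple()
    ):
        groups.append(
            GroupAdherence(
                group=name,
                consumed=consumed,
                recommended=recommended,
                ratio=consumed / recommended,
                met=consumed >= recommended,
            )
        )
    within = (
        None
        if profile.discretionary_max is None
        else servings.discretionary_servings_per_day <= profile.discretionary_max
    )
    return AdherenceReport(
        person_id=servings.person_id,
        profile_id=profile.profile_id,
        groups=tuple(groups),
        discretionary_consumed=servings.discretionary_servings_per_day,
        discretionary_limit=profile.discretionary_max,
        discretionary_within_limit=within,
    )


def read_profiles(path: str | Path) -> list[RecommendationProfile]:
    """Read recommendation profiles from YAML.

    Layout::

        profiles:
          - id: female-19-50
            grains: 6
            vegetables_legumes: 5
            fruit: 2
            dairy_alternatives: 2.5
            meat_alternatives: 2.5
            discretionary_max: 0
    """
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "profiles" not in doc:
        raise FormatError(f"{path}: expected a top-level 'profiles' list")
    out = []
    for entry in doc["profiles"]:
        out.append(
            RecommendationProfile(
                profile_id=str(entry.get("id", "")),
                recommended=FoodGroupVector(
                    *(float(entry.get(g, 0.0)) for g in GROUP_FIELDS)
                ),
                discretionary_max=(
                    None
                    if entry.get("discretionary_max") is None
                    else float(entry["discretionary_max"])
                ),
            )
        )
    return out


def score_intake_file(
    intakes_by_person: Mapping[str, Sequence[IntakeRecord]],
    table: ADGATTable,
) -> list[DailyServings]:
    """Score every person in an intake mapping, in mapping order."""
    return [
        aggregate_daily_servings(recs, table, person_id=pid)
        for pid, recs in intakes_by_person.items()
    ]
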