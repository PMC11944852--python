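"""Collapse matched records into summary-table rows.

When several database records match one FFQ item, their food-group
servings are combined by an unweighted arithmetic mean (consumption-
weighted averaging would require population consumption data that is not
reliably available).  An item is classified discretionary when strictly
more than a threshold proportion (default 20%) of its matched records
carry the discretionary flag; a discretionary item's servings are
quantified as mean energy density divided by the energy of one
discretionary serving (600 kJ).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import IntegrityError, ValidationError
from .food_model import (
    ADGATRow,
    ADGATTable,
    ADGFoodRecord,
    FoodGroupVector,
    GROUP_FIELDS,
)
from .matcher import MatchResult


@dataclass(frozen=True)
class DiscretionaryParams:
    """Parameters of the discretionary classification and quantification.

    proportion_threshold
        An item is discretionary when the flagged fraction of its matched
        records strictly exceeds this value.  Default 0.20.
    kj_per_serving
        Energy content of one discretionary serving, kJ.  Default 600.
    energy_basis
        Which matched records contribute to the mean energy density used
        in the servings quotient: ``"all"`` (default) or ``"flagged"``
        (discretionary-flagged records only).
    """

    proportion_threshold: float = 0.20
    kj_per_serving: float = 600.0
    energy_basis: str = "all"

    def __post_init__(self):
        if not 0 < self.proportion_threshold < 1:
            raise ValidationError(
                f"proportion_threshold must lie in (0, 1), got "
                f"{self.proportion_threshold!r}"
            )
        if self.kj_per_serving <= 0:
            raise ValidationError(
                f"kj_per_serving must be positive, got {self.kj_per_serving!r}"
            )
        if self.energy_basis not in ("all", "flagged"):
            raise ValidationError(
                f"energy_basis must be 'all' or 'flagged', got {self.energy_basis!r}"
            )

    @classmethod
    def from_dict(cls, doc) -> "DiscretionaryParams":
        allowed = {"proportion_threshold", "kj_per_serving", "energy_basis"}
        return cls(**{k: v for k, v in dict(doc).items() if k in allowed})


def average_groups(matched: Sequence[ADGFoodRecord]) -> FoodGroupVector:
    """Component-wise unweighted mean of group servings across records."""
    if not matched:
        raise ValidationError("cannot average an empty record list")
    n = len(matched)
    sums = [0.0] * len(GROUP_FIELDS)
    for rec in matched:
        for i, v in enumerate(rec.groups.as_tuple()):
            sums[i] += v
    return FoodGroupVector(*(s / n for s in sums))


def classify_discretionary(
    matched: Sequence[ADGFoodRecord], params: DiscretionaryParams | None = None
) -> bool:
    """True iff the flagged fraction strictly exceeds the threshold.

    Exactly 20% flagged (e.g. 1 of 5) does NOT classify as discretionary
    under the default parameters; 21 of 100 does.
    """
    if not matched:
        raise ValidationError("cannot classify an empty record list")
    params = params or DiscretionaryParams()
    flagged = sum(1 for r in matched if r.discretionary_flag)
    return flagged / len(matched) > params.proportion_threshold


def discretionary_servings(
    matched: Sequence[ADGFoodRecord],
    is_discretionary: bool,
    params: DiscretionaryParams | None = None,
) -> float:
    """Discretionary servings per 100 g: mean energy density / 600 kJ.

    Zero for items not classified discretionary, even when individual
    matched records carry the flag.
    """
    if not matched:
        raise ValidationError("cannot quantify an empty record list")
    params = params or DiscretionaryParams()
    if not is_discretionary:
        return 0.0
    if params.energy_basis == "flagged":
        basis = [r for r in matched if r.discretionary_flag]
        if not basis:  # cannot happen when classified via the >threshold rule
            basis = list(matched)
    else:
        basis = list(matched)
    mean_energy = sum(r.energy_kj_per_100g for r in basis) / len(basis)
    return mean_energy / params.kj_per_serving


def build_adgat_row(
    result: MatchResult, params: DiscretionaryParams | None = None
) -> ADGATRow:
    """One summary row from one match result."""
    params = params or DiscretionaryParams()
    matched = list(result.matched)
    groups = average_groups(matched)
    is_disc = classify_discretionary(matched, params)
    disc = discretionary_servings(matched, is_disc, params)
    return ADGATRow(
        item_name=result.item.item_name,
        form=result.item.expected_form,
        method=result.method,
        groups=groups,
        discretionary_servings_per_100g=disc,
    )


def build_adgat_table(
    results: Sequence[MatchResult], params: DiscretionaryParams | None = None
) -> ADGATTable:
    """One row per match result, input order preserved."""
    if not results:
        raise ValidationError("cannot build a summary table from zero results")
    table = ADGATTable()
    for result in results:
        try:
            table.append(build_adgat_row(result, params))
        except IntegrityError:
            raise IntegrityError(
                f"duplicate item name '{result.item.item_name}' in match results"
            ) from None
    return table
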