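"""Seeded synthetic ADG-style databases and intake files.

The real food-composition resource is a 5742-food download; nothing in
this package's tests requires it.  Instead the generators here emulate
its structure — generic-first comma-separated descriptions, "not further
defined" (NFD) summary records, raw/cooked variants, mixed-dish records,
all-zero records, discretionary flags and realistic energy densities — and
emit a manifest recording, for every planted target word or FFQ item, the
intended best match and its decoy structure.  Matcher tests therefore
have ground truth by construction.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import SyntheticSpecError
from .food_model import (
    ADGDatabase,
    ADGFoodRecord,
    FFQItemDef,
    FoodGroupVector,
    GROUP_FIELDS,
    IntakeRecord,
)
from .matcher import normalize_description

DEFAULT_VOCABULARY = (
    "butter", "bread", "apples", "chicken", "milk",
    "cheese", "rice", "carrots", "fish", "yoghurt",
)

#: Records planted per vocabulary word: NFD summary, two variants,
#: a raw decoy and a mixed-dish decoy.
FAMILY_SIZE = 5


@dataclass(frozen=True)
class SyntheticDBSpec:
    """Parameters of a synthetic ADG-style database.

    Fractions are honoured exactly (``round(fraction * n_foods)`` records
    of each kind); a spec whose fractions or vocabulary cannot fit in
    ``n_foods`` raises :class:`SyntheticSpecError`.
    """

    seed: int = 0
    n_foods: int = 200
    fraction_nfd: float = 0.15
    fraction_discretionary: float = 0.20
    fraction_all_zero: float = 0.05
    energy_range: tuple[float, float] = (100.0, 3000.0)
    term_vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY

    def __post_init__(self):
        for name in ("fraction_nfd", "fraction_discretionary", "fraction_all_zero"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SyntheticSpecError(f"{name} must lie in [0, 1], got {v!r}")
        lo, hi = self.energy_range
        if not (0 <= lo <= hi):
            raise SyntheticSpecError(
                f"energy_range must satisfy 0 <= min <= max, got {self.energy_range!r}"
            )
        if self.n_foods <= 0:
            raise SyntheticSpecError(f"n_foods must be positive, got {self.n_foods!r}")


def _random_groups(rng: np.random.Generator) -> FoodGroupVector:
    """One to two non-zero group servings, magnitudes typical of /100 g data."""
    values = [0.0] * len(GROUP_FIELDS)
    k = int(rng.integers(1, 3))
    for idx in rng.choice(len(GROUP_FIELDS), size=k, replace=False):
        values[idx] = float(np.round(rng.uniform(0.1, 3.5), 1))
    return FoodGroupVector(*values)


def _energy(rng: np.random.Generator, spec: SyntheticDBSpec) -> float:
    lo, hi = spec.energy_range
    return float(np.round(rng.uniform(lo, hi), 0))


def generate_synthetic_adg_db(
    spec: SyntheticDBSpec,
) -> tuple[ADGDatabase, dict]:
    """Generate a database with one planted family per vocabulary word.

    Each family holds an NFD summary record (the intended best match for a
    generic item searching that word), two variants, a raw decoy and a
    mixed-dish decoy.  Filler records carry synthetic names that match no
    vocabulary word.  The manifest records every planted id by role.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_foods
    words = tuple(spec.term_vocabulary)
    n_family = FAMILY_SIZE * len(words)
    if n_family > n:
        raise SyntheticSpecError(
            f"n_foods={n} cannot hold {len(words)} planted families "
            f"({n_family} records needed)"
        )
    n_zero = round(spec.fraction_all_zero * n)
    n_nfd = round(spec.fraction_nfd * n)
    n_extra_nfd = n_nfd - len(words)
    if n_extra_nfd < 0:
        raise SyntheticSpecError(
            f"fraction_nfd={spec.fraction_nfd} yields {n_nfd} NFD records, "
            f"fewer than the {len(words)} planted families require"
        )
    n_plain = n - n_family - n_zero - n_extra_nfd
    if n_plain < 0:
        raise SyntheticSpecError(
            f"n_foods={n} too small for the requested fractions and vocabulary"
        )

    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"F{counter:05d}"

    records: list[ADGFoodRecord] = []
    manifest: dict = {
        "families": {},
        "all_zero_ids": [],
        "extra_nfd_ids": [],
        "plain_ids": [],
        "discretionary_ids": [],
    }

    def add(description, groups, flag, energy):
        rec = ADGFoodRecord(
            food_id=next_id(),
            description=description,
            groups=groups,
            discretionary_flag=flag,
            energy_kj_per_100g=energy,
        )
        records.append(rec)
        return rec

    flag_eligible: list[int] = []  # indices eligible for a discretionary flag
    for word in words:
        fam = {}
        fam["target"] = add(
            f"{word.capitalize()}, plain, not further defined",
            _random_groups(rng), False, _energy(rng, spec),
        ).food_id
        fam["variants"] = []
        for tag in ("variety a", "variety b"):
            rec = add(
                f"{word.capitalize()}, {tag}",
                _random_groups(rng), False, _energy(rng, spec),
            )
            fam["variants"].append(rec.food_id)
            flag_eligible.append(len(records) - 1)
        fam["raw_decoy"] = add(
            f"{word.capitalize()}, flesh, raw",
            _random_groups(rng), False, _energy(rng, spec),
        ).food_id
        fam["mixed_decoy"] = add(
            f"{word.capitalize()}, stuffed with filling",
            _random_groups(rng), False, _energy(rng, spec),
        ).food_id
        manifest["families"][word] = fam

    for i in range(n_zero):
        rec = add(
            f"Zerofood{i:03d}, separable fat, grilled or roasted without fat",
            FoodGroupVector.zero(), False, _energy(rng, spec),
        )
        manifest["all_zero_ids"].append(rec.food_id)
    for i in range(n_extra_nfd):
        rec = add(
            f"Nfdfiller{i:03d}, not further defined",
            _random_groups(rng), False, _energy(rng, spec),
        )
        manifest["extra_nfd_ids"].append(rec.food_id)
    for i in range(n_plain):
        rec = add(
            f"Fillerfood{i:03d}, fresh", _random_groups(rng), False, _energy(rng, spec)
        )
        manifest["plain_ids"].append(rec.food_id)
        flag_eligible.append(len(records) - 1)

    n_disc = round(spec.fraction_discretionary * n)
    if n_disc > len(flag_eligible):
        raise SyntheticSpecError(
            f"fraction_discretionary={spec.fraction_discretionary} requires "
            f"{n_disc} flagged records but only {len(flag_eligible)} are eligible"
        )
    chosen = sorted(
        rng.choice(len(flag_eligible), size=n_disc, replace=False).tolist()
    )
    for pos in chosen:
        idx = flag_eligible[pos]
        old = records[idx]
        records[idx] = ADGFoodRecord(
            food_id=old.food_id,
            description=old.description,
            groups=old.groups,
            discretionary_flag=True,
            energy_kj_per_100g=old.energy_kj_per_100g,
        )
        manifest["discretionary_ids"].append(old.food_id)

    manifest["counts"] = {
        "n_foods": n,
        "n_families": len(words),
        "n_all_zero": n_zero,
        "n_nfd": n_nfd,
        "n_discretionary": n_disc,
    }
    return ADGDatabase(records), manifest


def generate_db_for_items(
    items: Sequence[FFQItemDef],
    seed: int = 0,
    *,
    n_fillers: int = 30,
    energy_range: tuple[float, float] = (100.0, 3000.0),
) -> tuple[ADGDatabase, dict]:
    """Generate a database guaranteed to contain >= 1 valid target per item.

    Generic items get an NFD summary record in primary position (the
    intended resolution); specific items get a variety record built from
    their own terms plus an excludable generic-NFD decoy.  Cooked and
    processed protein/starch items additionally get a raw decoy, and
    non-mixed items a mixed-dish decoy, exercising the exclusion rules.
    """
    spec = SyntheticDBSpec(seed=seed, energy_range=energy_range)
    rng = np.random.default_rng(seed)
    from .matcher import DEFAULT_COOKED_ASSUMED_TERMS  # avoid cycle at import

    cooked_assumed = {normalize_description(t) for t in DEFAULT_COOKED_ASSUMED_TERMS}
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"S{counter:05d}"

    records: list[ADGFoodRecord] = []
    manifest: dict = {"items": {}, "filler_ids": []}

    def add(description, *, zero=False, flag=False):
        rec = ADGFoodRecord(
            food_id=next_id(),
            description=description,
            groups=FoodGroupVector.zero() if zero else _random_groups(rng),
            discretionary_flag=flag,
            energy_kj_per_100g=_energy(rng, spec),
        )
        records.append(rec)
        return rec

    for item in items:
        terms = [normalize_description(t) for t in item.search_terms]
        t0 = terms[0]
        entry: dict = {"decoys": []}
        if item.is_specific:
            desc = ", ".join(terms) if len(terms) > 1 else f"{t0}, prepared"
            entry["target"] = add(desc).food_id
            entry["decoys"].append(add(f"{t0}, not further defined").food_id)
        else:
            entry["target"] = add(f"{t0}, plain, not further defined").food_id
            entry["expected_method"] = "not further defined"
        if item.expected_form != "mixed":
            entry["decoys"].append(add(f"{t0}, stuffed with filling").food_id)
        if item.expected_form in ("cooked", "processed") and t0 in cooked_assumed:
            entry["decoys"].append(add(f"{t0}, flesh, raw").food_id)
        manifest["items"][item.item_name] = entry

    for i in range(n_fillers):
        zero = i % 10 == 0
        rec = add(f"Fillerfood{i:03d}, fresh", zero=zero, flag=(i % 7 == 3))
        manifest["filler_ids"].append(rec.food_id)

    return ADGDatabase(records), manifest


@dataclass(frozen=True)
class IntakeSpec:
    """Log-normal g/day intake model, the typical right-skewed shape of
    dietary intake data.  ``mu``/``sigma`` parameterise the underlying
    normal; the distribution mean is ``exp(mu + sigma**2 / 2)``."""

    mu: float = math.log(30.0)
    sigma: float = 0.8

    @property
    def mean(self) -> float:
        return math.exp(self.mu + self.sigma**2 / 2)


def generate_intake_profile(
    seed: int,
    items: Sequence[FFQItemDef],
    n_persons: int,
    spec: IntakeSpec = IntakeSpec(),
) -> dict[str, list[IntakeRecord]]:
    """Deterministic per-seed intakes: every person reports every item."""
    if not items:
        raise SyntheticSpecError("need at least one item to generate intakes")
    rng = np.random.default_rng(seed)
    out: dict[str, list[IntakeRecord]] = {}
    for p in range(n_persons):
        pid = f"P{p + 1:04d}"
        draws = rng.lognormal(mean=spec.mu, sigma=spec.sigma, size=len(items))
        out[pid] = [
            IntakeRecord(item_name=it.item_name, grams_per_day=float(g))
            for it, g in zip(items, draws)
        ]
    return out
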