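"""Domain types and delimited-file I/O for the ADG-AT workflow.

The Australian Dietary Guidelines (ADG) database assigns every surveyed food
a number of food-group servings per 100 g across the five ADG food groups,
a discretionary flag, and an energy density (kJ/100 g).  This module defines
the in-memory types for that database, for FFQ item definitions, for
per-person intake records (g/day), and for the ADG-AT summary table
(servings per 100 g per FFQ item), together with CSV/YAML readers and
writers for each.

All numeric computation is carried at full float precision; rounding
(half-up, one decimal place) happens only when a summary table is written.
"""

from __future__ import annotations

import math
from collections.abc import Iterator, Mapping, Sequence
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd
import yaml

from .errors import FormatError, IntegrityError, ValidationError

#: The five ADG food groups, in canonical column order.
GROUP_FIELDS = (
    "grains",
    "vegetables_legumes",
    "fruit",
    "dairy_alternatives",
    "meat_alternatives",
)

#: Closed vocabulary for the expected form of an FFQ item.
FORMS = frozenset({"raw", "cooked", "raw/cooked", "processed", "mixed"})

#: Closed vocabulary for the matching method recorded in a summary row.
METHODS = frozenset({"single", "average", "not further defined"})

#: Canonical ADG database CSV columns.
DB_COLUMNS = (
    "food_id",
    "description",
    *GROUP_FIELDS,
    "discretionary_flag",
    "energy_kj_per_100g",
)

#: Canonical summary-table CSV columns.
TABLE_COLUMNS = ("item_name", "form", "method", *GROUP_FIELDS, "discretionary")


@dataclass(frozen=True)
class FoodGroupVector:
    """Servings per 100 g (or per day, in scoring contexts) across the five
    ADG food groups."""

    grains: float = 0.0
    vegetables_legumes: float = 0.0
    fruit: float = 0.0
    dairy_alternatives: float = 0.0
    meat_alternatives: float = 0.0

    def __post_init__(self):
        for name in GROUP_FIELDS:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"food group '{name}' must be finite, got {v!r}")
            if v < 0:
                raise ValidationError(f"food group '{name}' must be >= 0, got {v!r}")

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, name) for name in GROUP_FIELDS)

    def scale(self, factor: float) -> "FoodGroupVector":
        return FoodGroupVector(*(v * factor for v in self.as_tuple()))

    def __add__(self, other: "FoodGroupVector") -> "FoodGroupVector":
        return FoodGroupVector(
            *(a + b for a, b in zip(self.as_tuple(), other.as_tuple()))
        )

    @classmethod
    def zero(cls) -> "FoodGroupVector":
        return cls()


@dataclass(frozen=True)
class ADGFoodRecord:
    """One food of the ADG database: hierarchical description (most generic
    descriptor first), group servings per 100 g, discretionary flag and
    energy density."""

    food_id: str
    description: str
    groups: FoodGroupVector
    discretionary_flag: bool
    energy_kj_per_100g: float

    def __post_init__(self):
        if not self.description or not self.description.strip():
            raise ValidationError(f"record '{self.food_id}': description is empty")
        if not math.isfinite(self.energy_kj_per_100g) or self.energy_kj_per_100g < 0:
            raise ValidationError(
                f"record '{self.food_id}': energy_kj_per_100g must be a "
                f"non-negative finite number, got {self.energy_kj_per_100g!r}"
            )


class ADGDatabase:
    """Collection of :class:`ADGFoodRecord` keyed by ``food_id``.

    Iteration order is deterministic: sorted by ``food_id``.
    """

    def __init__(self, records: Sequence[ADGFoodRecord] = ()):
        self._records: dict[str, ADGFoodRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: ADGFoodRecord) -> None:
        if rec.food_id in self._records:
            raise IntegrityError(f"duplicate food_id '{rec.food_id}'")
        self._records[rec.food_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, food_id: str) -> bool:
        return food_id in self._records

    def __getitem__(self, food_id: str) -> ADGFoodRecord:
        return self._records[food_id]

    def __iter__(self) -> Iterator[ADGFoodRecord]:
        for fid in sorted(self._records):
            yield self._records[fid]

    def __eq__(self, other) -> bool:
        if not isinstance(other, ADGDatabase):
            return NotImplemented
        return list(self) == list(other)


@dataclass(frozen=True)
class FFQItemDef:
    """Definition of one FFQ output item.

    ``search_terms`` drive candidate recall in the matcher;
    ``expected_form`` records the form the questionnaire implies (Table-style
    "Form" column values); ``is_specific`` is true when the item names a
    specific variety (e.g. wholemeal bread), which blocks matching to
    generic "not further defined" summary records.
    """

    item_name: str
    search_terms: tuple[str, ...]
    expected_form: str
    is_specific: bool = False

    def __post_init__(self):
        if not self.search_terms:
            raise ValidationError(f"item '{self.item_name}': no search terms")
        object.__setattr__(self, "search_terms", tuple(self.search_terms))
        if self.expected_form not in FORMS:
            raise ValidationError(
                f"item '{self.item_name}': unknown form '{self.expected_form}' "
                f"(expected one of {sorted(FORMS)})"
            )


@dataclass(frozen=True)
class IntakeRecord:
    """One reported intake: item name and grams per day."""

    item_name: str
    grams_per_day: float

    def __post_init__(self):
        if not math.isfinite(self.grams_per_day) or self.grams_per_day < 0:
            raise ValidationError(
                f"intake '{self.item_name}': grams_per_day must be a "
                f"non-negative finite number, got {self.grams_per_day!r}"
            )


@dataclass(frozen=True)
class ADGATRow:
    """One summary row: an FFQ item's form, matching method, mean group
    servings per 100 g, and discretionary servings per 100 g."""

    item_name: str
    form: str
    method: str
    groups: FoodGroupVector
    discretionary_servings_per_100g: float

    def __post_init__(self):
        if self.form not in FORMS:
            raise ValidationError(
                f"row '{self.item_name}': unknown form '{self.form}'"
            )
        if self.method not in METHODS:
            raise ValidationError(
                f"row '{self.item_name}': unknown method '{self.method}'"
            )
        d = self.discretionary_servings_per_100g
        if not math.isfinite(d) or d < 0:
            raise ValidationError(
                f"row '{self.item_name}': discretionary servings must be a "
                f"non-negative finite number, got {d!r}"
            )


class ADGATTable:
    """Ordered collection of :class:`ADGATRow`, one per FFQ item."""

    def __init__(self, rows: Sequence[ADGATRow] = ()):
        self._rows: list[ADGATRow] = []
        self._index: dict[str, int] = {}
        for row in rows:
            self.append(row)

    def append(self, row: ADGATRow) -> None:
        if row.item_name in self._index:
            raise IntegrityError(f"duplicate item_name '{row.item_name}'")
        self._index[row.item_name] = len(self._rows)
        self._rows.append(row)

    def __len__(self) -> int:
        return len(self._rows)

    def __iter__(self) -> Iterator[ADGATRow]:
        return iter(self._rows)

    def __contains__(self, item_name: str) -> bool:
        return item_name in self._index

    def __getitem__(self, item_name: str) -> ADGATRow:
        try:
            return self._rows[self._index[item_name]]
        except KeyError:
            raise KeyError(f"unknown item '{item_name}'") from None

    def item_names(self) -> list[str]:
        return [r.item_name for r in self._rows]

    def __eq__(self, other) -> bool:
        if not isinstance(other, ADGATTable):
            return NotImplemented
        return self._rows == other._rows


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _coerce_float(value, *, row: int, column: str) -> float:
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise ValidationError(
            f"row {row}: column '{column}' is not numeric: {value!r}"
        ) from None
    if not math.isfinite(v):
        raise ValidationError(f"row {row}: column '{column}' is not finite: {value!r}")
    if v < 0:
        raise ValidationError(f"row {row}: column '{column}' is negative: {value!r}")
    return v


def _coerce_flag(value, *, row: int, column: str) -> bool:
    s = str(value).strip().lower()
    if s in {"1", "true", "yes", "y"}:
        return True
    if s in {"0", "false", "no", "n"}:
        return False
    raise ValidationError(
        f"row {row}: column '{column}' is not a 0/1 flag: {value!r}"
    )


def read_adg_database(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> ADGDatabase:
    """Read an ADG-style food composition database from CSV.

    ``dialect`` optionally remaps canonical column names to the names used
    in the file, e.g. ``{"food_id": "Food ID", "grains": "Grain serves"}``,
    so an exported copy of the real FSANZ workbook can be loaded without
    code changes.

    Raises :class:`FormatError` for missing mandatory columns,
    :class:`IntegrityError` for duplicate food ids, and
    :class:`ValidationError` (citing the data row number, 1-based) for
    negative or non-numeric serving/energy values.
    """
    dialect = dict(dialect or {})
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = {canon: dialect.get(canon, canon) for canon in DB_COLUMNS}
    missing = [src for src in colmap.values() if src not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s): {', '.join(sorted(missing))}"
        )

    db = ADGDatabase()
    for i, raw in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, raw))
        groups = FoodGroupVector(
            *(
                _coerce_float(rowd[colmap[g]], row=i, column=g)
                for g in GROUP_FIELDS
            )
        )
        rec = ADGFoodRecord(
            food_id=str(rowd[colmap["food_id"]]).strip(),
            description=str(rowd[colmap["description"]]),
            groups=groups,
            discretionary_flag=_coerce_flag(
                rowd[colmap["discretionary_flag"]], row=i, column="discretionary_flag"
            ),
            energy_kj_per_100g=_coerce_float(
                rowd[colmap["energy_kj_per_100g"]], row=i, column="energy_kj_per_100g"
            ),
        )
        db.add(rec)
    return db


def write_adg_database(db: ADGDatabase, path: str | Path) -> None:
    """Write a database to canonical CSV (records sorted by food_id)."""
    rows = []
    for rec in db:
        rows.append(
            {
                "food_id": rec.food_id,
                "description": rec.description,
                **dict(zip(GROUP_FIELDS, rec.groups.as_tuple())),
                "discretionary_flag": int(rec.discretionary_flag),
                "energy_kj_per_100g": rec.energy_kj_per_100g,
            }
        )
    pd.DataFrame(rows, columns=list(DB_COLUMNS)).to_csv(path, index=False)


def read_ffq_items(path: str | Path) -> list[FFQItemDef]:
    """Read FFQ item definitions from a YAML file.

    Expected layout::

        items:
          - name: Butter
            terms: [butter]
            form: processed
            specific: false
    """
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "items" not in doc:
        raise FormatError(f"{path}: expected a top-level 'items' list")
    items: list[FFQItemDef] = []
    seen: set[str] = set()
    for entry in doc["items"]:
        name = entry.get("name")
        if not name:
            raise ValidationError(f"{path}: item entry without a name: {entry!r}")
        if name in seen:
            raise IntegrityError(f"{path}: duplicate item name '{name}'")
        seen.add(name)
        items.append(
            FFQItemDef(
                item_name=name,
                search_terms=tuple(entry.get("terms") or ()),
                expected_form=entry.get("form", ""),
                is_specific=bool(entry.get("specific", False)),
            )
        )
    return items


def write_ffq_items(items: Sequence[FFQItemDef], path: str | Path) -> None:
    doc = {
        "items": [
            {
                "name": it.item_name,
                "terms": list(it.search_terms),
                "form": it.expected_form,
                "specific": it.is_specific,
            }
            for it in items
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (2.65 -> 2.7)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def write_adgat_table(
    table: ADGATTable, path: str | Path, *, full_precision: bool = False
) -> None:
    """Write a summary table to CSV.

    Numeric cells are rendered half-up to one decimal place, matching the
    published presentation.  With ``full_precision=True`` a sidecar column
    set (``*_exact``) preserves the unrounded values.
    """
    rows = []
    for r in table:
        base = {
            "item_name": r.item_name,
            "form": r.form,
            "method": r.method,
            **{
                g: f"{round_half_up(v):.1f}"
                for g, v in zip(GROUP_FIELDS, r.groups.as_tuple())
            },
            "discretionary": f"{round_half_up(r.discretionary_servings_per_100g):.1f}",
        }
        if full_precision:
            base.update(
                {
                    f"{g}_exact": repr(v)
                    for g, v in zip(GROUP_FIELDS, r.groups.as_tuple())
                }
            )
            base["discretionary_exact"] = repr(r.discretionary_servings_per_100g)
        rows.append(base)
    columns = list(TABLE_COLUMNS)
    if full_precision:
        columns += [f"{g}_exact" for g in GROUP_FIELDS] + ["discretionary_exact"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def read_adgat_table(path: str | Path) -> ADGATTable:
    """Read a summary table written by :func:`write_adgat_table`.

    When sidecar ``*_exact`` columns are present they take precedence over
    the rounded presentation cells.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )
    exact = all(f"{g}_exact" in df.columns for g in GROUP_FIELDS)
    table = ADGATTable()
    for i, raw in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, raw))
        suffix = "_exact" if exact else ""
        groups = FoodGroupVector(
            *(
                _coerce_float(rowd[f"{g}{suffix}"], row=i, column=g)
                for g in GROUP_FIELDS
            )
        )
        disc_col = "discretionary_exact" if exact else "discretionary"
        table.append(
            ADGATRow(
                item_name=rowd["item_name"],
                form=rowd["form"],
                method=rowd["method"],
                groups=groups,
                discretionary_servings_per_100g=_coerce_float(
                    rowd[disc_col], row=i, column="discretionary"
                ),
            )
        )
    return table


def read_intakes(path: str | Path) -> dict[str, list[IntakeRecord]]:
    """Read a per-person intake CSV (person_id, item_name, grams_per_day).

    Returns an ordered mapping person_id -> intake records, in file order.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    needed = ("person_id", "item_name", "grams_per_day")
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )
    out: dict[str, list[IntakeRecord]] = {}
    for i, raw in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, raw))
        rec = IntakeRecord(
            item_name=rowd["item_name"],
            grams_per_day=_coerce_float(
                rowd["grams_per_day"], row=i, column="grams_per_day"
            ),
        )
        out.setdefault(str(rowd["person_id"]), []).append(rec)
    return out


def write_intakes(
    intakes: Mapping[str, Sequence[IntakeRecord]], path: str | Path
) -> None:
    rows = [
        {
            "person_id": pid,
            "item_name": rec.item_name,
            "grams_per_day": repr(rec.grams_per_day),
        }
        for pid, recs in intakes.items()
        for rec in recs
    ]
    pd.DataFrame(rows, columns=["person_id", "item_name", "grams_per_day"]).to_csv(
        path, index=False
    )
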