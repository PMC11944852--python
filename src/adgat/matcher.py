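"""Rule-based matching of FFQ items to food-composition records.

The pipeline mirrors the broad-then-narrow flow used when the ADG-AT was
constructed by hand:

1. **string search** — recall every database record whose normalized
   description contains at least one of the item's search terms;
2. **exclusions** — drop all-zero records, raw forms of foods consumed
   cooked, mixed dishes when a single food is implied, and generic
   "not further defined" (NFD) summary records when the item is specific;
3. **selection** — prefer an NFD summary record in primary position for
   generic items (it represents the average of all variants of the food),
   otherwise prefer records whose first descriptor carries a search term;
4. **method classification** — label the resolution "not further defined",
   "single", or "average".

Every candidate ever considered is recorded in an audit trail with its
disposition and the rule that decided it, so a run can be reviewed the way
two independent coders would cross-check each other.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .errors import AdgatError, UnmatchedItemError, ValidationError
from .food_model import ADGDatabase, ADGFoodRecord, FFQItemDef

NFD_PHRASE = "not further defined"

#: Foods assumed to be consumed cooked: animal proteins and starchy
#: vegetables/pulses.  Raw-form database records are excluded for items
#: whose search terms intersect this vocabulary.
DEFAULT_COOKED_ASSUMED_TERMS = (
    "beef", "veal", "lamb", "pork", "chicken", "turkey", "bacon", "ham",
    "sausage", "sausages", "fish", "salmon", "tuna", "sardine", "egg",
    "eggs", "potato", "potatoes", "pumpkin", "peas", "beans", "lentils",
    "chick peas", "chickpea", "rice", "pasta", "noodles", "porridge",
)

DEFAULT_RAW_KEYWORDS = ("raw", "uncooked")

DEFAULT_DISH_KEYWORDS = ("stuffed", "casserole", "with", "dish", "pie", "soup")


@dataclass(frozen=True)
class MatchConfig:
    """Tunable vocabularies and toggles for the matching pipeline.

    The keyword lists are configuration rather than code because the
    protocol gives exemplars, not exhaustive lists.  ``overrides`` pins an
    explicit list of food ids for items where automated matching is
    insufficient (the protocol resolved those by researcher consensus).
    """

    raw_keywords: tuple[str, ...] = DEFAULT_RAW_KEYWORDS
    dish_keywords: tuple[str, ...] = DEFAULT_DISH_KEYWORDS
    cooked_assumed_terms: tuple[str, ...] = DEFAULT_COOKED_ASSUMED_TERMS
    prefer_nfd: bool = True
    overrides: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "MatchConfig":
        kwargs = {}
        for key in ("raw_keywords", "dish_keywords", "cooked_assumed_terms"):
            if key in doc:
                kwargs[key] = tuple(doc[key])
        if "prefer_nfd" in doc:
            kwargs["prefer_nfd"] = bool(doc["prefer_nfd"])
        if "overrides" in doc:
            kwargs["overrides"] = {
                k: tuple(v) for k, v in dict(doc["overrides"]).items()
            }
        return cls(**kwargs)


@dataclass(frozen=True)
class Candidate:
    record: ADGFoodRecord
    matched_terms: frozenset[str]
    primary_position: bool
    is_nfd: bool


@dataclass(frozen=True)
class AuditEntry:
    food_id: str
    disposition: str  # "kept" or "excluded:<rule>"
    rule: str


@dataclass
class CandidateSet:
    """Candidates for one item at some stage of the pipeline, plus the
    audit trail accumulated so far."""

    item: FFQItemDef
    candidates: list[Candidate]
    audit: list[AuditEntry] = field(default_factory=list)
    used_nfd: bool = False

    def exclude(self, cand: Candidate, rule: str, citation: str) -> None:
        self.audit.append(AuditEntry(cand.record.food_id, f"excluded:{rule}", citation))

    def finalize_audit(self) -> None:
        decided = {e.food_id for e in self.audit}
        for cand in self.candidates:
            if cand.record.food_id not in decided:
                self.audit.append(AuditEntry(cand.record.food_id, "kept", "survivor"))


@dataclass(frozen=True)
class MatchResult:
    item: FFQItemDef
    matched: tuple[ADGFoodRecord, ...]
    method: str
    audit: tuple[AuditEntry, ...]


_NON_TOKEN = re.compile(r"[^a-z0-9,\s]")
_COMMA_SPACING = re.compile(r"\s*,\s*")
_MULTI_SPACE = re.compile(r"\s+")


def normalize_description(text: str) -> str:
    """Normalize a description for matching.

    Lowercases; collapses punctuation other than commas (dashes, slashes,
    ampersands...) to spaces; collapses runs of whitespace; strips.  Comma
    structure is preserved because commas delimit descriptor hierarchy
    (most generic term first).  Idempotent.
    """
    t = text.lower()
    t = _NON_TOKEN.sub(" ", t)
    t = _COMMA_SPACING.sub(", ", t)
    t = _MULTI_SPACE.sub(" ", t)
    return t.strip()


def _normalized_terms(item: FFQItemDef) -> list[str]:
    terms = [normalize_description(t) for t in item.search_terms]
    return [t for t in terms if t]


def _contains_word(haystack: str, word: str) -> bool:
    return re.search(rf"(?<![a-z0-9]){re.escape(word)}(?![a-z0-9])", haystack) is not None


def string_search(item: FFQItemDef, db: ADGDatabase) -> CandidateSet:
    """Recall all records containing >= 1 search term as a substring.

    ``primary_position`` is set when the first comma-delimited descriptor
    begins with one of the terms; ``is_nfd`` when the description contains
    the "not further defined" phrase.  Candidates are ordered by
    descending matched-term count, then food_id.
    """
    if len(db) == 0:
        raise ValidationError("cannot match against an empty database")
    terms = _normalized_terms(item)
    if not terms:
        raise ValidationError(f"item '{item.item_name}' has no usable search terms")
    cands: list[Candidate] = []
    for rec in db:
        desc = normalize_description(rec.description)
        matched = frozenset(t for t in terms if t in desc)
        if not matched:
            continue
        first = desc.split(",", 1)[0].strip()
        primary = any(first.startswith(t) for t in terms)
        cands.append(
            Candidate(
                record=rec,
                matched_terms=matched,
                primary_position=primary,
                is_nfd=NFD_PHRASE in desc,
            )
        )
    cands.sort(key=lambda c: (-len(c.matched_terms), c.record.food_id))
    return CandidateSet(item=item, candidates=cands)


def apply_exclusions(cands: CandidateSet, config: MatchConfig | None = None) -> CandidateSet:
    """Apply the exclusion rules, recording each removal in the audit.

    (a) all five group servings zero and non-discretionary — the record
        carries no information (pure-fat trimmings and the like);
    (b) raw-form records for items consumed cooked (animal proteins and
        starchy vegetables/pulses);
    (c) mixed-dish records when the item implies a single food;
    (d) generic NFD summary records when the item names a specific variety.
    """
    config = config or MatchConfig()
    item = cands.item
    item_terms = set(_normalized_terms(item))
    cooked_assumed = item.expected_form in ("cooked", "processed") and bool(
        item_terms & {normalize_description(t) for t in config.cooked_assumed_terms}
    )
    kept: list[Candidate] = []
    for cand in cands.candidates:
        desc = normalize_description(cand.record.description)
        if (
            all(v == 0 for v in cand.record.groups.as_tuple())
            and not cand.record.discretionary_flag
        ):
            cands.exclude(cand, "all-zero", "all five group servings zero, non-discretionary")
        elif cooked_assumed and any(
            _contains_word(desc, kw) for kw in config.raw_keywords
        ):
            cands.exclude(cand, "raw-form", "raw form of a food consumed cooked")
        elif item.expected_form != "mixed" and any(
            _contains_word(desc, kw) for kw in config.dish_keywords
        ):
            cands.exclude(cand, "mixed-dish", "mixed dish where a single food is implied")
        elif item.is_specific and cand.is_nfd:
            cands.exclude(cand, "general-nfd", "general description for a specific item")
        else:
            kept.append(cand)
    return CandidateSet(item=item, candidates=kept, audit=cands.audit)


def apply_selection(cands: CandidateSet, config: MatchConfig | None = None) -> CandidateSet:
    """Apply the selection preferences after exclusions.

    For a generic item with an NFD summary record in primary position, the
    NFD record(s) stand in for all variants of the food; otherwise records
    whose first descriptor carries a search term are preferred; otherwise
    all survivors stand.
    """
    config = config or MatchConfig()
    item = cands.item
    survivors = cands.candidates
    nfd_primary = [c for c in survivors if c.is_nfd and c.primary_position]
    used_nfd = False
    if config.prefer_nfd and not item.is_specific and nfd_primary:
        keep = sorted(nfd_primary, key=lambda c: c.record.food_id)
        used_nfd = True
        rule, citation = "not-nfd-summary", "NFD summary record preferred for generic item"
    elif any(c.primary_position for c in survivors):
        keep = [c for c in survivors if c.primary_position]
        rule, citation = "not-primary-position", "search term not in primary position"
    else:
        keep = list(survivors)
        rule = citation = ""
    keep_ids = {c.record.food_id for c in keep}
    for cand in survivors:
        if cand.record.food_id not in keep_ids:
            cands.exclude(cand, rule, citation)
    return CandidateSet(item=item, candidates=keep, audit=cands.audit, used_nfd=used_nfd)


def classify_method(selected: CandidateSet) -> str:
    """Label how the item resolved: via an NFD summary record, a single
    record, or an average of several."""
    if not selected.candidates:
        selected.finalize_audit()
        raise UnmatchedItemError(selected.item.item_name, selected.audit)
    if selected.used_nfd:
        return "not further defined"
    if len(selected.candidates) == 1:
        return "single"
    return "average"


def match_item(
    item: FFQItemDef, db: ADGDatabase, config: MatchConfig | None = None
) -> MatchResult:
    """Run the full four-stage pipeline for one item.

    Deterministic for fixed inputs and config.  Raises
    :class:`UnmatchedItemError` (carrying the audit trail) when no record
    survives.  An explicit override pin in the config short-circuits the
    pipeline.
    """
    config = config or MatchConfig()
    if item.item_name in config.overrides:
        ids = config.overrides[item.item_name]
        missing = [fid for fid in ids if fid not in db]
        if missing:
            raise ValidationError(
                f"override for '{item.item_name}' names unknown food id(s): "
                f"{', '.join(missing)}"
            )
        records = tuple(db[fid] for fid in sorted(ids))
        if not records:
            raise ValidationError(f"override for '{item.item_name}' is empty")
        all_nfd = all(
            NFD_PHRASE in normalize_description(r.description) for r in records
        )
        method = (
            "not further defined"
            if all_nfd
            else ("single" if len(records) == 1 else "average")
        )
        audit = tuple(
            AuditEntry(r.food_id, "kept", "explicit override pin") for r in records
        )
        return MatchResult(item=item, matched=records, method=method, audit=audit)

    cands = string_search(item, db)
    cands = apply_exclusions(cands, config)
    selected = apply_selection(cands, config)
    method = classify_method(selected)
    selected.finalize_audit()
    return MatchResult(
        item=item,
        matched=tuple(c.record for c in selected.candidates),
        method=method,
        audit=tuple(selected.audit),
    )


def match_all(
    items: Sequence[FFQItemDef],
    db: ADGDatabase,
    config: MatchConfig | None = None,
) -> tuple[list[MatchResult], list[UnmatchedItemError]]:
    """Match every item; collect unmatched-item errors instead of raising."""
    results: list[MatchResult] = []
    failures: list[UnmatchedItemError] = []
    for item in items:
        try:
            results.append(match_item(item, db, config))
        except UnmatchedItemError as exc:
            failures.append(exc)
    return results, failures
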