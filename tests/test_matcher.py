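"""Matcher unit and property tests, including an independent brute-force
oracle implementing the stated matching rules by direct enumeration."""

import random
import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adgat import (
    ADGDatabase,
    FFQItemDef,
    MatchConfig,
    UnmatchedItemError,
    ValidationError,
    apply_exclusions,
    apply_selection,
    classify_method,
    match_item,
    normalize_description,
    string_search,
)

from conftest import make_record


# ---------------------------------------------------------------------------
# Independent brute-force oracle
# ---------------------------------------------------------------------------

RAW_KEYWORDS = ("raw", "uncooked")
DISH_KEYWORDS = ("stuffed", "casserole", "with", "dish", "pie", "soup")
COOKED_ASSUMED = ("beef", "chicken", "fish", "potato", "beans", "eggs")


def oracle_normalize(s):
    out = []
    for ch in s.lower():
        if (ch.isascii() and ch.isalnum()) or ch == ",":
            out.append(ch)
        else:
            out.append(" ")
    t = "".join(out)
    while "  " in t:
        t = t.replace("  ", " ")
    t = re.sub(r" ?, ?", ", ", t)
    while "  " in t:
        t = t.replace("  ", " ")
    return t.strip()


def _has_word(desc, word):
    return re.search(rf"(?<![a-z0-9]){re.escape(word)}(?![a-z0-9])", desc) is not None


def oracle_match(item, records):
    """Plain enumeration of the four matching stages.

    Returns (sorted food ids, method) or None when no record survives.
    """
    terms = [oracle_normalize(t) for t in item.search_terms]
    # stage 1: recall
    cands = []
    for rec in records:
        desc = oracle_normalize(rec.description)
        if any(t in desc for t in terms):
            first = desc.split(",")[0].strip()
            cands.append(
                {
                    "rec": rec,
                    "desc": desc,
                    "primary": any(first.startswith(t) for t in terms),
                    "nfd": "not further defined" in desc,
                }
            )
    # stage 2: exclusions
    cooked_item = item.expected_form in ("cooked", "processed") and any(
        t in COOKED_ASSUMED for t in terms
    )
    survivors = []
    for c in cands:
        if all(v == 0 for v in c["rec"].groups.as_tuple()) and not c["rec"].discretionary_flag:
            continue
        if cooked_item and any(_has_word(c["desc"], k) for k in RAW_KEYWORDS):
            continue
        if item.expected_form != "mixed" and any(
            _has_word(c["desc"], k) for k in DISH_KEYWORDS
        ):
            continue
        if item.is_specific and c["nfd"]:
            continue
        survivors.append(c)
    # stage 3: selection
    nfd_primary = [c for c in survivors if c["nfd"] and c["primary"]]
    used_nfd = False
    if not item.is_specific and nfd_primary:
        survivors = nfd_primary
        used_nfd = True
    elif any(c["primary"] for c in survivors):
        survivors = [c for c in survivors if c["primary"]]
    if not survivors:
        return None
    # stage 4: method
    if used_nfd:
        method = "not further defined"
    elif len(survivors) == 1:
        method = "single"
    else:
        method = "average"
    return sorted(c["rec"].food_id for c in survivors), method


def random_small_db(rng, max_records=10):
    """Random database exercising NFD records, raw/dish decoys, zero
    records and discretionary flags."""
    heads = ["butter", "bread", "beef", "apple", "fish"]
    tails = [
        "plain", "not further defined", "raw", "stuffed with rice",
        "variety a", "grilled", "separable fat", "salted", "pie filling",
    ]
    n = rng.randint(1, max_records)
    records = []
    for i in range(n):
        head = rng.choice(heads)
        ntail = rng.randint(0, 2)
        desc = ", ".join([head] + rng.sample(tails, ntail))
        zero = rng.random() < 0.25
        groups = (
            (0, 0, 0, 0, 0)
            if zero
            else tuple(round(rng.uniform(0, 2), 1) for _ in range(5))
        )
        records.append(
            make_record(
                f"R{i:02d}", desc, groups,
                discretionary=rng.random() < 0.3,
                energy=round(rng.uniform(100, 3000)),
            )
        )
    return records


def random_item(rng):
    heads = ["butter", "bread", "beef", "apple", "fish"]
    terms = tuple(rng.sample(heads, rng.randint(1, 3)))
    form = rng.choice(["raw", "cooked", "raw/cooked", "processed", "mixed"])
    return FFQItemDef("Item", terms, form, is_specific=rng.random() < 0.3)


ORACLE_CONFIG = MatchConfig(
    raw_keywords=RAW_KEYWORDS,
    dish_keywords=DISH_KEYWORDS,
    cooked_assumed_terms=COOKED_ASSUMED,
)


class TestNormalize:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Beef, all cuts, separable fat", "beef, all cuts, separable fat"),
            ("  Cheese—Ricotta  ", "cheese ricotta"),
            ("Bread,  commercial,fresh", "bread, commercial, fresh"),
            ("", ""),
        ],
    )
    def test_examples(self, raw, expected):
        assert normalize_description(raw) == expected

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(st.text(max_size=60))
    def test_idempotent(self, text):
        once = normalize_description(text)
        assert normalize_description(once) == once


class TestStringSearch:
    def test_nfd_butter_candidate_flags(self, butter_item):
        db = ADGDatabase(
            [make_record("F1", "Butter, plain, not further defined")]
        )
        cs = string_search(butter_item, db)
        assert len(cs.candidates) == 1
        cand = cs.candidates[0]
        assert cand.primary_position and cand.is_nfd

    def test_mixed_dish_is_still_a_candidate_at_this_stage(self):
        item = FFQItemDef("Peppers (capsicum)", ("capsicum",), "raw/cooked")
        db = ADGDatabase(
            [make_record("F1", "Capsicum, stuffed with meat & rice")]
        )
        cs = string_search(item, db)
        assert [c.record.food_id for c in cs.candidates] == ["F1"]

    def test_empty_database_is_an_error(self, butter_item):
        with pytest.raises(ValidationError):
            string_search(butter_item, ADGDatabase())

    def test_matches_equal_brute_force_scan_on_random_db(self):
        rng = random.Random(42)
        for _ in range(50):
            records = random_small_db(rng, max_records=50)
            item = random_item(rng)
            db = ADGDatabase(records)
            cs = string_search(item, db)
            got = sorted(c.record.food_id for c in cs.candidates)
            terms = [oracle_normalize(t) for t in item.search_terms]
            expected = sorted(
                r.food_id
                for r in records
                if any(t in oracle_normalize(r.description) for t in terms)
            )
            assert got == expected

    def test_ordering_by_matched_term_count_then_id(self):
        item = FFQItemDef("X", ("butter", "bread"), "processed")
        db = ADGDatabase(
            [
                make_record("A2", "Butter, plain"),
                make_record("A1", "Bread and butter pudding base"),
            ]
        )
        cs = string_search(item, db)
        assert [c.record.food_id for c in cs.candidates] == ["A1", "A2"]


class TestExclusions:
    def exclusion_ids(self, cs):
        return {
            e.food_id: e.disposition for e in cs.audit if e.disposition != "kept"
        }

    def test_all_zero_non_discretionary_excluded(self):
        item = FFQItemDef("Beef", ("beef",), "cooked")
        db = ADGDatabase(
            [
                make_record(
                    "F1",
                    "Beef, all cuts, separable fat, grilled or roasted without fat",
                    (0, 0, 0, 0, 0), False,
                ),
                make_record("F2", "Beef, rump steak, grilled", (0, 0, 0, 0, 1.5)),
            ]
        )
        cs = apply_exclusions(string_search(item, db))
        assert self.exclusion_ids(cs) == {"F1": "excluded:all-zero"}

    def test_zero_groups_but_discretionary_is_retained(self, butter_item):
        # beverages like beer carry zero group servings but a positive
        # discretionary contribution; they must survive
        db = ADGDatabase(
            [make_record("F1", "Butter, salted", (0, 0, 0, 0, 0), True, 3000)]
        )
        cs = apply_exclusions(string_search(butter_item, db))
        assert [c.record.food_id for c in cs.candidates] == ["F1"]

    def test_raw_form_excluded_for_cooked_animal_protein(self):
        item = FFQItemDef("Chicken", ("chicken",), "cooked")
        db = ADGDatabase(
            [
                make_record("F1", "Chicken, breast, flesh, raw", (0, 0, 0, 0, 1.2)),
                make_record("F2", "Chicken, breast, grilled", (0, 0, 0, 0, 1.1)),
            ]
        )
        cs = apply_exclusions(string_search(item, db))
        assert self.exclusion_ids(cs) == {"F1": "excluded:raw-form"}

    def test_raw_form_kept_for_raw_cooked_item(self):
        item = FFQItemDef("Tomatoes", ("tomatoes",), "raw/cooked")
        db = ADGDatabase(
            [make_record("F1", "Tomatoes, common, raw", (0, 1.4, 0, 0, 0))]
        )
        cs = apply_exclusions(string_search(item, db))
        assert len(cs.candidates) == 1

    def test_mixed_dish_excluded_when_single_food_implied(self):
        item = FFQItemDef("Peppers (capsicum)", ("capsicum",), "raw/cooked")
        db = ADGDatabase(
            [
                make_record("F1", "Capsicum, stuffed with meat & rice", (0.5, 0.5, 0, 0, 0.5)),
                make_record("F2", "Capsicum, green, fresh", (0, 1.3, 0, 0, 0)),
            ]
        )
        cs = apply_exclusions(string_search(item, db))
        assert self.exclusion_ids(cs) == {"F1": "excluded:mixed-dish"}

    def test_nfd_excluded_for_specific_item(self):
        item = FFQItemDef(
            "Bread—wholemeal", ("bread", "wholemeal"), "processed", is_specific=True
        )
        db = ADGDatabase(
            [
                make_record("F1", "Bread, commercial, fresh, not further defined",
                            (2.7, 0, 0, 0, 0)),
                make_record("F2", "Bread, wholemeal, commercial", (2.7, 0, 0, 0, 0)),
            ]
        )
        cs = apply_exclusions(string_search(item, db))
        assert self.exclusion_ids(cs) == {"F1": "excluded:general-nfd"}

    def test_audit_conservation(self):
        rng = random.Random(7)
        for _ in range(30):
            records = random_small_db(rng)
            item = random_item(rng)
            cs = string_search(item, ADGDatabase(records))
            n_candidates = len(cs.candidates)
            after = apply_exclusions(cs, ORACLE_CONFIG)
            n_excluded = sum(
                1 for e in after.audit if e.disposition.startswith("excluded")
            )
            assert len(after.candidates) + n_excluded == n_candidates


class TestSelection:
    def test_nfd_preferred_for_generic_item(self, butter_item, butter_family_db):
        cs = apply_selection(
            apply_exclusions(string_search(butter_item, butter_family_db))
        )
        assert [c.record.food_id for c in cs.candidates] == ["B01"]
        assert cs.used_nfd

    def test_no_primary_position_keeps_all_survivors(self):
        item = FFQItemDef("Citrus", ("citrus",), "raw")
        db = ADGDatabase(
            [
                make_record("F1", "Orange, citrus, fresh", (0, 0, 0.7, 0, 0)),
                make_record("F2", "Mandarin, citrus, fresh", (0, 0, 0.7, 0, 0)),
            ]
        )
        cs = apply_selection(apply_exclusions(string_search(item, db)))
        assert len(cs.candidates) == 2 and not cs.used_nfd

    def test_primary_position_preferred_when_no_nfd(self):
        item = FFQItemDef("Apples", ("apple",), "raw")
        db = ADGDatabase(
            [
                make_record("F1", "Apple, red, fresh", (0, 0, 0.7, 0, 0)),
                make_record("F2", "Pie, apple, bakery", (0.9, 0, 0.2, 0, 0)),
            ]
        )
        cs = apply_selection(apply_exclusions(string_search(item, db)))
        assert [c.record.food_id for c in cs.candidates] == ["F1"]


class TestClassifyAndMatch:
    def test_method_labels(self, butter_item, butter_family_db):
        result = match_item(butter_item, butter_family_db)
        assert result.method == "not further defined"
        assert [r.food_id for r in result.matched] == ["B01"]

        item = FFQItemDef("Apricots", ("apricot",), "raw")
        db = ADGDatabase([make_record("F1", "Apricot, fresh", (0, 0, 0.7, 0, 0))])
        assert match_item(item, db).method == "single"

        item = FFQItemDef("Bacon", ("bacon",), "cooked")
        db = ADGDatabase(
            [
                make_record("F1", "Bacon, middle rasher, grilled", (0, 0, 0, 0, 1.4), True, 1100),
                make_record("F2", "Bacon, shortcut, grilled", (0, 0, 0, 0, 1.5), True, 1200),
                make_record("F3", "Bacon, breakfast style", (0, 0, 0, 0, 1.3), True, 1150),
            ]
        )
        assert match_item(item, db).method == "average"

    def test_unmatched_error_carries_audit(self):
        item = FFQItemDef("Beef", ("beef",), "cooked")
        db = ADGDatabase(
            [make_record("F1", "Beef, separable fat", (0, 0, 0, 0, 0), False)]
        )
        with pytest.raises(UnmatchedItemError) as exc:
            match_item(item, db)
        assert exc.value.audit[0].disposition == "excluded:all-zero"

    def test_override_pins_explicit_records(self, butter_family_db, butter_item):
        cfg = MatchConfig(overrides={"Butter": ("B02", "B03")})
        result = match_item(butter_item, butter_family_db, cfg)
        assert [r.food_id for r in result.matched] == ["B02", "B03"]
        assert result.method == "average"

    def test_deterministic_across_runs(self, butter_item, butter_family_db):
        r1 = match_item(butter_item, butter_family_db)
        r2 = match_item(butter_item, butter_family_db)
        assert r1 == r2

    def test_monotonicity_unrelated_record_never_changes_result(self):
        rng = random.Random(11)
        for _ in range(25):
            records = random_small_db(rng)
            item = random_item(rng)
            db1 = ADGDatabase(records)
            db2 = ADGDatabase(
                records
                + [make_record("ZZZ", "Quandongberry, fresh", (0, 0, 0.5, 0, 0))]
            )
            try:
                r1 = match_item(item, db1, ORACLE_CONFIG)
                ids1 = [r.food_id for r in r1.matched]
                method1 = r1.method
            except UnmatchedItemError:
                ids1 = method1 = None
            try:
                r2 = match_item(item, db2, ORACLE_CONFIG)
                ids2 = [r.food_id for r in r2.matched]
                method2 = r2.method
            except UnmatchedItemError:
                ids2 = method2 = None
            assert (ids1, method1) == (ids2, method2)

    def test_equals_brute_force_oracle_on_small_databases(self):
        """match_item agrees with a direct enumeration of the stated rules
        on randomized databases of <= 10 records and <= 3 search terms."""
        rng = random.Random(2024)
        checked_methods = set()
        for _ in range(500):
            records = random_small_db(rng)
            item = random_item(rng)
            expected = oracle_match(item, records)
            try:
                result = match_item(item, ADGDatabase(records), ORACLE_CONFIG)
                got = (sorted(r.food_id for r in result.matched), result.method)
            except UnmatchedItemError:
                got = None
            assert got == expected
            if expected:
                checked_methods.add(expected[1])
        # the random cases must exercise every method label
        assert checked_methods == {"single", "average", "not further defined"}
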