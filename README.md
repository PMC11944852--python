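# adgat — Australian Dietary Guidelines Adherence Tool

`adgat` evaluates adherence to the Australian Dietary Guidelines (ADG) from
food-frequency-questionnaire (FFQ) data. The ADG database assigns every food
in the national food-composition resource a number of food-group servings
per 100 g across the five ADG food groups — grains, vegetables/legumes,
fruit, dairy/alternatives, meat/alternatives — plus a discretionary flag
and an energy density (kJ/100 g). FFQ outputs, however, arrive as grams per
day of questionnaire items with no food-composition identifier attached.
`adgat` bridges the two:

1. **Match** — a rule-based record-linkage pipeline links each FFQ item to
   one or more database foods: exact-substring search over the hierarchical
   food descriptions, followed by exclusion rules (all-zero records; raw
   forms of foods consumed cooked; mixed dishes where a single food is
   implied; generic records when the item names a specific variety) and
   selection rules (prefer a "not further defined" summary record in the
   primary description position for generic items, else records with a
   search term in primary position). Every candidate's fate is recorded in
   an audit trail.
2. **Aggregate** — multiple matches are collapsed by an unweighted mean of
   food-group servings. An item is classified *discretionary* (energy-dense,
   nutrient-poor) when strictly more than 20% of its matched records carry
   the discretionary flag, and its discretionary servings per 100 g are
   quantified as mean energy density divided by 600 kJ (the energy of one
   discretionary serving).
3. **Score** — reported intakes convert linearly to servings per day:
   `servings/day = Σ_items g/day × (servings/100 g) / 100`, compared against
   user-supplied age-sex recommendation profiles (food groups are adequacy
   floors, discretionary intake a ceiling).

The package ships the 101-item adherence summary table for the Dietary
Questionnaire for Epidemiological Studies (DQES v2) as a checksum-pinned
reference resource, plus seeded synthetic database/intake generators so the
whole pipeline is testable without the external database download.

Intended users: nutrition epidemiologists scoring DQES cohort data against
the guidelines, and anyone adapting the matching protocol to another FFQ or
national food-composition database.

## Worked example

Score a person who reports 20 g/day of butter and 150 g/day of apples:

```python
from adgat import IntakeRecord, aggregate_daily_servings, load_reference_table

table = load_reference_table()          # 101 rows, servings per 100 g
servings = aggregate_daily_servings(
    [IntakeRecord("Butter", 20.0), IntakeRecord("Apples", 150.0)],
    table, person_id="P1",
)
print(round(servings.groups.fruit, 2))                    # 1.05
print(round(servings.discretionary_servings_per_day, 2))  # 1.0
```

Apples carry 0.7 fruit servings/100 g, so 150 g/day is 1.05 fruit
servings/day. Butter carries 5.0 discretionary servings/100 g (it is
energy-dense: 5.0 = 3000 kJ / 600 kJ per discretionary serving), so
20 g/day is exactly one discretionary serving per day.

The same workflow from the shell:

```bash
adgat simulate --seed 3 --out fixtures/        # synthetic database bundle
adgat build --adg-db fixtures/database.csv --items fixtures/items.yaml \
            --out table.csv --audit audit.csv  # run the matching pipeline
adgat score --intake intake.csv --out report.csv   # uses the packaged table
adgat validate                                 # reference checksum + invariants
```

`adgat build` exits non-zero and withholds the table if any item fails to
match (see the audit CSV for the rule that removed each candidate);
`--allow-partial` writes the matched subset instead.

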