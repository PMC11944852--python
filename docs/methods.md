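# Methods

## The matching model

The tool treats FFQ-to-database linkage as deterministic, rule-based record
linkage over hierarchical food descriptions. A database description is a
comma-separated descriptor list with the most generic term first
("Chicken, breast, flesh, raw"); an FFQ item carries an ordered list of
search terms, an expected form (raw / cooked / raw/cooked / processed /
mixed) and a specificity flag (true when the item names a particular
variety, e.g. wholemeal bread).

Matching is broad-then-narrow:

1. **Recall.** A record is a candidate when its normalized description
   contains at least one normalized search term as a substring.
   Normalization lowercases, collapses punctuation other than commas to
   spaces, collapses whitespace and preserves comma structure; it is
   idempotent. Recall is deliberately permissive — precision is restored
   by the later stages.
2. **Exclusion**, applied in order, each removal audited:
   (a) records whose five group servings are all zero *and* that are not
   discretionary-flagged (they carry no information; note that beverages
   such as beer have all-zero group servings but a positive discretionary
   contribution, so the flag condition is essential);
   (b) raw-form records (keyword list, default "raw", "uncooked", matched
   as whole words) when the item is expected cooked or processed and its
   terms intersect the configurable animal-protein/starchy-vegetable
   vocabulary — these foods are consumed cooked, with nutrient retention
   assumed already encoded in the database's cooked records;
   (c) mixed-dish records (keyword list, default "stuffed", "casserole",
   "with", "dish", "pie", "soup") when the item's expected form is not
   "mixed";
   (d) generic "not further defined" (NFD) summary records when the item
   is specific.
3. **Selection.** For a generic item with a surviving NFD record whose
   first descriptor begins with a search term ("primary position"), the
   NFD record(s) are kept alone — an NFD record is the database's own
   average over all variants of a food, so it is the best single
   representative. Otherwise primary-position records are preferred;
   otherwise all survivors stand.
4. **Method label.** "not further defined" when the NFD branch resolved
   the item, "single" for exactly one surviving record, "average" for two
   or more.

Ties are broken lexicographically by food id everywhere, making the whole
pipeline a pure function of (inputs, config). Per-item override pins are
available for items where automated rules cannot reproduce an expert
judgement; the keyword vocabularies are configuration because the protocol
defines them by exemplar rather than exhaustively.

## Aggregation and discretionary foods

Multiple matches collapse to a single row by an unweighted component-wise
mean of group servings. Consumption-weighted averaging would be preferable
in principle but requires reliable population consumption weights, which
are not generally available; the unweighted mean is therefore the model,
not a fallback.

Discretionary classification uses a strict threshold: an item is
discretionary iff flagged/total > 0.20 (exactly 20% flagged does not
trigger). Discretionary servings per 100 g are mean energy density over
the matched records divided by 600 kJ, the defined energy content of one
discretionary serving. Two open choices are exposed as parameters:

- `proportion_threshold` (default 0.20) and `kj_per_serving` (default
  600 kJ) in `DiscretionaryParams`;
- `energy_basis`: whether the mean energy is taken over all matched
  records (default, consistent with the unweighted group-serving mean) or
  only the discretionary-flagged subset.

Non-discretionary items report 0 discretionary servings even when some
matched records are flagged, keeping the summary table internally
consistent. All aggregation runs at full float precision; presentation
rounding (half-up, one decimal) happens only at serialization, with
optional full-precision sidecar columns.

## Scoring and adherence

Daily servings are linear in grams: each reported item contributes
g/day × servings-per-100 g / 100, summed per food group and for the
discretionary component. The computation is additive and
permutation-invariant by construction; duplicate (person, item) records
are summed with a logged warning. Discretionary servings are reported
alongside, not inside, the five food groups: mixed dishes legitimately
contribute to both, and how to treat the overlap is an interpretive
choice left to the analyst.

Adherence compares servings/day with a recommendation profile
(servings/day per food group, optional discretionary ceiling). "Met" is
consumed ≥ recommended for food groups and consumed ≤ limit for
discretionary intake. Recommendation numbers are always user-supplied
configuration — they vary by age-sex stratum and are not part of the
packaged data.

## Packaged reference data

The package ships the 101-row adherence summary table (servings per 100 g
of the five food groups and discretionary foods per DQES item) as CSV,
with a pinned SHA-256 checksum so transcription drift fails loudly, and a
matching 101-entry item-definition file. Item search terms were derived
from the item names (em-dash qualifiers mark specific varieties; commas
and parentheticals yield alternate terms) and are user-editable — they
are a curated starting point, not ground truth. Scoring a 100 g/day
intake of any item against this table returns exactly the item's
per-100 g row, which is the package's primary end-to-end check.

## Synthetic data

Two seeded generators make every stage testable without the external
5742-food download:

- a **word-family generator** (`SyntheticDBSpec`): for each vocabulary
  word it plants an NFD summary record, two variants, a raw decoy and a
  mixed-dish decoy, then fills to `n_foods` with all-zero decoys, extra
  NFD records and neutral fillers. Fractions (`fraction_nfd`,
  `fraction_discretionary`, `fraction_all_zero`) are honoured exactly via
  `round(fraction × n_foods)`; impossible specs raise. The manifest
  records every planted id by role, so matcher tests have ground truth by
  construction.
- an **items-driven generator** that plants at least one valid target per
  FFQ item definition (an NFD record in primary position for generic
  items, a variety record plus an excludable generic-NFD decoy for
  specific ones, with raw and mixed-dish decoys where the exclusion rules
  apply).

Intakes are drawn log-normal (default median 30 g/day, σ = 0.8), the
typical right-skewed shape of dietary intake data; every synthetic person
reports every item, as an FFQ output would.

What the synthetic data does *not* emulate: real descriptor vocabulary
breadth (thousands of distinct foods, brand names, spelling variants),
correlated intakes across items, item non-response, and the true energy/serving
joint distribution of the real database. Passing tests therefore
demonstrate that the rules are implemented as stated and are internally
consistent — not that the shipped search terms reproduce an expert's
matches on the real database, which requires the optional external
download and review of the audit trail.

## Numerical and design notes

- Threshold comparison is a strict `>` on the flagged fraction; at the
  default threshold the 1-in-5 and 20-in-100 boundary cases are exactly
  representable, so no epsilon is needed.
- Presentation rounding is decimal half-up (2.65 → 2.7), computed via
  `decimal` on the shortest repr to avoid binary-float surprises.
- Empty candidate sets after exclusion/selection raise an
  unmatched-item error carrying the full audit trail; builds fail closed
  (no partial table without `--allow-partial`).
- Problem sizes in the test-suite property checks (≤ 10-record databases
  for oracle equivalence, 100-record match sets for the threshold sweep,
  1000 randomized algebra cases, 80–280-record end-to-end bundles) were
  chosen to exhaust the rule branches at desk scale; the pipeline itself
  is linear in database size per item.

## Known limitations

- Food groups are handled at their broadest level: no wholegrain/refined
  split, no dairy-fat tiers, no dietary-variety scoring.
- Unweighted averaging over matched records can misrepresent items whose
  variants have very uneven consumption.
- Exact-substring recall cannot bridge spelling variants or synonyms;
  per-item overrides are the intended escape hatch.
- The discretionary energy denominator treats all discretionary foods
  identically; alcohol's distinct serving definitions are not modelled.
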