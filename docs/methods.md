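# Methods

## The identification methods

**Address linkage.** The algorithm is a postcode gate followed by three
confirmation criteria. The gate is exact postcode equality between a
patient's current address record and a register entry active at the index
date; it deliberately over-selects, because English postcodes routinely
cover a care home and its private neighbours. Confirmation is (a) equality
of normalised building-name token sequences, tried first on the address
house-name field and then on its other free-text fields; (b) equality with a
*derived* house number — a number carried by at least `number_threshold`
(default 10) name-matched address records of one register entry, which then
identifies the home within its postcode; or (c) at least `size_threshold`
(default 10) patients aged 65+ registered at the identical address record in
the postcode of an old-age home. Name matching is **exact token-sequence
equality after normalisation**, not fuzzy distance: normalisation
uppercases, deletes apostrophes, maps other punctuation to token breaks,
canonicalises a fixed abbreviation table (ST↔SAINT, HSE↔HOUSE, RD↔ROAD) and
drops a fixed stop-token set (THE, CARE, HOME, NURSING, RESIDENTIAL). Exact
matching after normalisation keeps the positive-predictive-value story
provable — every flag can be traced to a literal register name — at the cost
of missing token-reordered variants; a fuzzy matcher could be added behind
the same interface but is deliberately not the default. The precise
normalisation table used by any production system is unpublished; ours is a
documented stand-in with the same structure.

Two readings of criterion (b) are possible; we count **distinct address
records per (register entry, number) pair**, require the name match to sit
in the entry's own postcode before counting, and expose the threshold as a
parameter so the alternative is reachable.

Date filtering uses closed intervals; a missing `registered_to` means the
home is still registered, a missing `valid_to` means the address is current.
Patients under 65 who match are reported in the log but classified
`private_home` by default (younger matches are usually live-in carers,
family members or neighbours). When one address matches several active homes
the care-home status is identical either way; the nursing categorisation
uses the entry with name evidence, then the lexicographically smallest
location id, and the tie is logged. A register entry asserting both nursing
flags is contradictory; it is categorised `care_home_misc` and logged.

**Household rule.** "At least three other people aged 65 or older" is
implemented literally: a flagged patient needs ≥ `min_other_members`
(default 3) *other* qualifying members, i.e. a household with ≥ 4 residents
aged 65+. The stricter and looser readings that appear in practice are
reachable through the parameter. Membership is counted from the resolved
patient rows, never from the stored household-size field (which may include
members registered elsewhere); discrepancies are logged. Household id 0
encodes invalid/missing and is excluded, with the exclusion counted in the
data-quality report.

**Coded events.** Windows are closed at both ends; `past_year` is
`[index_date − 1 year, index_date]` with a 29 February anniversary mapping
to 28 February. The shipped PRIMIS list has six SNOMED codes; the
incentivised subset (160734000 "Lives in a nursing home", 394923006 "Lives
in a residential home") is the pair practices are paid to maintain. Rows
with unparseable dates are rejected and counted, never silently dropped.

**Comparison.** Percentages round half-up at the printed precision (2 dp for
prevalence, 1 dp for overlap shares, 0 dp for the "lacking coded events"
statements); half-up is asserted at an exact tie in the tests because
floating-point banker's rounding differs exactly there. Where a published
abstract and results section disagree at the last digit (32.0 vs 32.1 for
53,210/165,845 = 32.084…%), the half-up value 32.1 is taken as canonical.
The Venn summary recomputes the inclusion–exclusion identity on every call
and fails loudly if the flag frame is inconsistent. All overlap statistics
are derivable from marginal counts alone (`OverlapCounts.intersections`), so
printed tables can be fed back through the same arithmetic.

## The synthetic generator

The generator emulates a GP-registered population observed at a single index
date (default 2020-02-01). What it reproduces, and why:

| parameter | default | role |
|---|---|---|
| `n_patients` | 20,000 | registered population (35% aged 65+) |
| `n_care_homes` | 40 | register size |
| `prop_resident_65plus` | 0.03 | planted residency among 65+ (observed band ≈ 2–3.5%) |
| `care_home_size_distribution` | 6–45 beds | includes homes < 10 beds so the size rule has designed false negatives |
| `p_historical_home` | 0.10 | register entries closed before the index date |
| `p_stale_address` | 0.25 | residents whose GP address was never updated; the linkage's dominant false-negative source. No quantitative rate is published; 0.25 is asserted as plausible and places the downstream prevalence table inside the observed band |
| `p_name_variant` | 0.10 | corrupted house-name text (abbreviation, punctuation, suffix drop, token reorder, case) |
| `p_per_resident_records` | 0.25 | homes whose residents each carry their own copy of the address record (exercises the derived-number rule) |
| `p_coded_given_resident` | 0.55 | under-coding: observed data imply roughly half of residents carry a code |
| `p_coded_given_nonresident` | 0.002 | false coding |
| `p_temporary_stay` | 0.10 | respite-style stays, labelled in ground truth |
| `p_invalid_household` | 0.01 | household id 0 |
| `p_shared_postcode` | 0.05 | private dwellings sharing a care-home postcode |
| `demographics_odds` | F 2.0, >80 10.1, white 2.9, dementia 28.7, stroke 3.9 | odds ratios of resident vs 65+ base rates, back-calculated from published characteristic contrasts |

Structural choices: care homes are filled to their bed count in random order
(real homes run near capacity; spreading residents thinly would starve the
household and size rules at small n); residents of one home share its
household id and, unless the home keeps per-resident records, one address
record. Non-residents are grouped age-assortatively — over-65s mostly live
alone or in couples, with all-elder households of 4+ rare (~0.4%) but
present, because they are the household rule's realistic false-positive
source. Temporary-stay residents and stale-address residents stay registered
at a private dwelling; temporary stays are excluded from sensitivity
denominators by default (`score_against_truth`), since no method is expected
to capture them, but they count as true positives for PPV. Within one
postcode a house number identifies a single dwelling, so private dwellings
sharing a care-home postcode draw numbers from a range disjoint from the
care homes' own; postcodes are synthetic tokens with a realistic
outward/inward shape, never real postcodes. Ages are completed years at the
index date; generated dates of birth invert the age arithmetic exactly.

What the generator does **not** emulate: free-text address idiosyncrasies
beyond the five corruption classes, multi-practice coverage of one home,
migration over time (everything is a snapshot), non-old-age institutions
(prisons, staffed housing for younger adults), and incentive-driven coding
uptake after the index date. Passing tests therefore show the algorithms are
correct implementations of their rules and recover planted parameters under
this error model — not that the rules are accurate on any particular real
dataset, where the published comparison itself had no gold standard.

## Numerical and engineering choices

- Determinism: every generator stage draws from
  `default_rng([seed, stage])`; a fixed seed fixes every output table
  byte-for-byte, and the pipeline writes no timestamps, so re-runs are
  bit-identical.
- All classifiers are permutation-invariant in their input row order
  (asserted in tests), and no operation mutates its inputs; outputs are
  written atomically (temp file + rename).
- CSV dialect is fixed (UTF-8, comma, header row, ISO-8601 dates, LF);
  SNOMED codes and postcodes are read as strings to survive round-trips.
- Degenerate inputs: empty codelists, empty populations and empty flagged
  sets raise explicit errors rather than emitting NaN or 0; empty
  characteristic columns are NaN, never silent zeros.
- Problem sizes: unit fixtures use 3,000–20,000 patients; parameter-recovery
  checks use 50,000 patients (≈ 500 planted residents), which keeps binomial
  3-SE tolerances around ±0.06 on a sensitivity of 0.7 while the whole suite
  runs in well under a minute.

## Known limitations

- Exact-after-normalisation name matching misses token reorderings by
  design; the generator plants them (`reorder` corruption) so the miss rate
  is visible in scores.
- The size rule (criterion c) cannot see homes below the threshold, and the
  derived-number rule only activates for homes with many per-resident
  records; both are faithful to their rules, not deficiencies of the
  implementation.
- The household identifier is treated as given; its derivation from address
  history is out of scope, as is any modelling of infection, mortality or
  platform governance.
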