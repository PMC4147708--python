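# Methods

## Scope and data model

The package models a single-jurisdiction branded food-composition database:
one record per SKU keyed by its UPC/GTIN barcode, each carrying a nutrient
panel per 100 g (foods) or per 100 ml (beverages), a category assignment,
and optionally a serving size. Optional nutrients (fiber, calcium, fvnl
composition) have an explicit absent state distinct from zero — in CSV an
empty cell, in JSON `null` — because the imputation rules depend on knowing
*that* a value was not declared, not just that it is small. Panels are
validated on construction (non-negative values, saturated fat ≤ total fat,
sugars ≤ carbohydrate) and re-validated on load, with row-level
diagnostics.

Sodium is the stored quantity (it is what nutrition panels declare); salt
is derived at the standard NaCl conversion, salt g = sodium mg × 2.5/1000,
immediately before classification. Barcode check digits follow the GTIN
mod-10 rule for lengths 8/12/13/14; validation is advisory because
real-world crowdsourced barcodes occasionally fail the checksum.

## Traffic-light classification

Cutoffs are configuration with defaults equal to the UK FSA signpost
tables: per 100 g for foods (green ≤ 3.0 / red > 20.0 g total fat,
≤ 1.5 / > 5.0 g saturated fat, ≤ 5.0 / > 12.5 g sugars, ≤ 0.30 / > 1.50 g
salt) and per 100 ml for drinks (≤ 1.5 / > 10.0, ≤ 0.75 / > 2.5,
≤ 2.5 / > 6.3, ≤ 0.30 / > 1.50). Foods additionally carry per-portion red
criteria (> 21.0 / 6.0 / 15.0 / 2.40 g per portion); drinks have none.

Numerical choices: comparisons are performed on exact values with no prior
rounding, since the cutoff tables give exact numbers and no rounding rule;
green/amber upper bounds are inclusive, red strictly exclusive, matching
the printed column boundaries. The per-portion amount is computed as
`value × serving / 100` in that order so that decimal servings land exactly
on portion thresholds. The per-portion override is applied whenever a food
has a serving size (configurable off); the full UK guidance conditions the
portion criteria on portion size, but that refinement is out of scope here,
so the override is unconditional by default and can only move a colour
toward red.

## Nutrient-profile scoring

Scoring categories: 1 beverages, 3 oils/spreads/margarine/butter plus
cheese strictly above 320 mg calcium/100 g, 2 everything else. Because
oils reach category 3 unconditionally while cheese is calcium-gated, the
category table carries both an `npsc_category3_member` flag and an
`is_cheese` flag; a cheese record without calcium (observed or imputed) is
a scoring error, by design — the gate cannot be decided without it.

Point tables are monotone threshold lists with strict-exceed semantics: a
component's points equal the number of thresholds its amount strictly
exceeds, capped by the list length. The shipped defaults use uniform
increments at the published FSANZ granularity — energy 335 kJ (cap 10),
saturated fat 1 g (30), sugars 4.5 g (10), sodium 90 mg (30), protein 1.6 g
(5), fiber 0.9 g (2) — and a V-point lookup awarding 1/2/5/8 points above
40/60/67/80 %fvnl. The value set {0, 1, 2, 5, 8} is enforced for any
configured lookup. One table set serves all three scoring categories by
default; category-specific tables are representable in configuration. The
FSANZ rule withholding protein points from high-baseline foods (baseline
> 13) without high V points is implemented but disabled by default, as a
configuration switch.

The final score is the exact integer identity baseline − V − P − F,
asserted at construction of every score object. Lower scores order
"healthier" throughout the switch engine.

## Imputation

Category statistics (arithmetic means of observed fiber and calcium) are
computed once from the raw database; imputed values never feed back into
the means, avoiding any fixed-point ambiguity. Rules, per missing field:
fiber → 0 where the category cannot contain fiber, else the category mean
(error if no observations); calcium → category mean, required only for
cheese categories; fvnl → 0 % where the category has no appreciable
fruit/vegetable content, else the category's configured default percentage
(explicit configuration keeps the assigned values auditable). A category
mean is trusted from a single observation; the observation count is
reported so downstream users can apply their own threshold. Imputation is
idempotent, never alters observed values, and flags every filled field
through to the score's `imputed_inputs`.

## Switch engine

"Healthier" is strictly better on the ranking key: a lower final score in
profile mode, strictly less sodium in salt mode (secondary key: final
score). Equal-key products are never offered — a lateral move is not a
switch. Recommendations stay within the query's category; ties beyond the
key break deterministically by name then barcode. Excluded categories
return their standard advisory message with an empty list. The default
result cap is 10 and configurable; no pagination.

## Crowdsourcing

Submissions are keyed by barcode with three labelled, order-independent
photo slots. Repeat scans of the same unknown barcode coalesce (photo
references unioned). Data entry is modelled as attaching a validated
record to a pending submission — no OCR. Merging adds entered records with
fresh barcodes and skips collisions with a report; it never overwrites, so
merging is idempotent and the database grows by exactly the number of
non-colliding entered submissions.

## Synthetic data generator

The generator emulates the *structure* of a surveyed branded database, not
any real market's distributions: ~10 supermarket-style category profiles
(bread, cereal, cheese, oils, snacks, soup, eggs, sugar-sweetened soft
drinks, juice, milk) with uniform nutrient ranges chosen to be plausible
per 100 g/ml and to exercise all three scoring categories, the
switch-excluded path, and the portion-override path. Saturated fat is drawn
as a fraction of total fat and sugars as a fraction of carbohydrate, so
panel invariants hold by construction; barcodes are GTIN-13 with valid
check digits; one seeded generator drives everything, so a config + seed
pair reproduces the database exactly.

Missingness defaults mirror the real availability pattern: fvnl
composition is never declared (rate 1.0, later imputed from category
defaults), while fiber and calcium are partially declared (rate 0.3 each —
partial coverage chosen once as realistic, since exact fractions vary by
market). What passing tests on these fixtures shows is that the *rules*
behave correctly under realistic structure; they say nothing about any
real market's nutrient values, category taxonomy (~700 categories in
production-scale databases vs ~10 profiles here), or label transcription
error, which the generator does not model.

## Problem sizes and verification

The test suite exercises the switch engine against an independent
brute-force filter/sort oracle on a seeded database of ≥ 1,000 records
(30 categories), and the boundary script sweeps classification grids at
0.1 g / 0.01 g / 1 mg resolution — fine enough that the reported boundary
equals the printed cutoff exactly under the inclusive/exclusive semantics
above. Property tests (hypothesis, derandomised) cover classifier and
score monotonicity, round-trip I/O equality over random synthetic
databases, and check-digit self-consistency.

## Known limitations

No fuzzy name search, no cross-category recommendations, no ingredient or
allergen modelling (so no gluten-oriented mode), no Health Star Rating,
no portion-size preconditions on the portion override, and no model-based
imputation beyond category means and fixed rules. Category-specific point
tables and the protein-cap rule exist in configuration but are not
defaulted.
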