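# nutriswitch

A reusable engine for interpretive food labelling and healthier-product
recommendation over a barcode-keyed, branded food-composition database.
It is aimed at public-health nutrition informatics: the computational core
behind "scan a barcode, see at-a-glance nutrition signposting, get healthier
same-category alternatives" tools, plus the database plumbing such tools
need (validation, missing-nutrient imputation, crowdsourced intake of
unknown barcodes, synthetic test databases).

## What it computes

**Traffic-light labels.** Each product is signposted green / amber / red for
total fat, saturated fat, sugars and salt, with an uncoloured energy figure,
using the UK FSA signpost cutoffs — separate tables per 100 g (foods) and
per 100 ml (drinks), plus per-portion "high" criteria for foods with a known
serving size (e.g. total fat > 21.0 g/portion forces red). Salt is derived
from declared sodium: salt g = sodium mg × 2.5 / 1000. Boundary semantics
are exact: a food at 3.0 g total fat/100 g is green, 3.0 + ε is amber.

**Nutrient-profile score (NPSC-style).** Foods score in three categories
(1 beverages; 2 other foods; 3 oils, spreads, margarine, butter, and cheese
with > 320 mg calcium/100 g). Baseline points accrue for energy (0–10),
saturated fat (0–30), total sugars (0–10) and sodium (0–30); modifying
points are subtracted for fruit/vegetable/nut/legume content
(V ∈ {0, 1, 2, 5, 8}, with concentrated components double-weighted:
%fvnl = 100·(nonconc + 2·conc)/(nonconc + 2·conc + non-fvnl)), protein
(0–5) and fiber (0–2):

    final score = baseline − V − P − F        (lower = healthier)

Point increments are configuration; the shipped defaults use the published
FSANZ granularity (335 kJ, 1 g, 4.5 g, 90 mg, 1.6 g, 0.9 g per point).

**Imputation.** Fiber, calcium and fvnl content are incompletely declared
on real labels. Missing values are filled per auditable rules — zero for
categories that cannot contain the nutrient, the category mean of observed
values otherwise (calcium only where the cheese calcium gate needs it),
and a configured category default for fvnl — and every filled field is
flagged through to the score.

**Switch recommendations.** Same-category alternatives with a strictly
lower profile score (or, in salt mode, strictly less sodium, tie-broken by
score), sorted best-first. Excluded categories (e.g. sugar-sweetened soft
drinks) return a standard advisory message instead.

**Crowdsourcing.** Unknown barcodes produce a submission prompt (three
photo slots: front of pack, nutrition panel, ingredients); entered records
merge idempotently into a new database release.

## Worked example

```python
from nutriswitch import FoodRecord, NutrientPanel, label_record

bar = FoodRecord(
    upc="9300000000017", name="fruit muesli bar", brand="Example Foods",
    category_id="snack-bars", is_beverage=False,
    panel=NutrientPanel(energy_kj=1650, protein_g=7, total_fat_g=15,
                        saturated_fat_g=6.2, carbohydrate_g=60, sugars_g=28,
                        sodium_mg=90),
    serving_size_g=45.0)
for nutrient, color in label_record(bar).colors.items():
    print(nutrient.value, color.value)
```

prints

```
total_fat amber
saturated_fat red
sugars red
salt green
```

— fat sits in the medium band (3.0 < 15 ≤ 20 g/100 g), saturated fat and
sugars exceed their red cutoffs (5.0 and 12.5 g/100 g), and 90 mg sodium is
0.225 g salt, under the 0.30 g green maximum. See `examples/` for scoring,
switching, imputation, crowdsourcing and database generation walkthroughs,
and `nutriswitch --help` for the command-line interface
(`scan`, `label`, `score`, `switch`, `submit`, `synth`, `db ...`).

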