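"""Crowdsource flow: unknown barcode -> submission -> data entry -> merge.

A scan that misses the database asks the user for three photographs; once a
data-entry step transcribes the label, the record merges into the next
database release.
"""

from nutriswitch import (FoodRecord, GeneratorConfig, NutrientPanel,
                         ScoredDatabase, SubmissionQueue, generate_database,
                         merge_submissions, record_missing_scan, scan)

db = generate_database(GeneratorConfig(seed=5, n_categories=6,
                                       products_per_category=(5, 8)))
engine = ScoredDatabase.prepare(db)

unknown = "9312345678907"
prompt = scan(engine, unknown)
print(f"scan miss for {prompt.upc}; please photograph: "
      f"{', '.join(prompt.requested_photos)}")

queue = SubmissionQueue()
record_missing_scan(queue, db, unknown,
                    {"front_of_pack": "img/001.jpg", "nip": "img/002.jpg",
                     "ingredients": "img/003.jpg"})

# data-entry transcribes the photographed nutrition panel into a record
category_id = next(iter(db.categories))
queue.enter_record(unknown, FoodRecord(
    upc=unknown, name="new product", brand="Example Foods",
    category_id=category_id, is_beverage=db.categories[category_id].is_beverage,
    panel=NutrientPanel(energy_kj=1000, protein_g=8, total_fat_g=3,
                        saturated_fat_g=1, carbohydrate_g=45, sugars_g=4,
                        sodium_mg=400, fiber_g=3)))

new_db, report = merge_submissions(db, queue)
print(f"merged: +{report.added} records ({len(db)} -> {len(new_db)}), "
      f"skipped {report.skipped}")

# Merging the same queue again adds nothing (idempotent), and a submission
# colliding with an existing barcode is skipped and reported, never
# silently overwritten.
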