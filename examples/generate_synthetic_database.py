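"""Generate a seeded synthetic food database and write it to CSV.

The generator stands in for a surveyed branded-food database: supermarket
style categories, per-100 g/ml nutrient panels, valid barcode check digits,
and realistic missingness (fvnl never declared; fiber and calcium partial).
"""

from pathlib import Path

from nutriswitch import GeneratorConfig, generate_database, save_database

cfg = GeneratorConfig(seed=2026, n_categories=12, products_per_category=(15, 30))
db = generate_database(cfg)

out = Path("scratch/synth_demo")
out.mkdir(parents=True, exist_ok=True)
save_database(db, out / "records.csv", out / "categories.csv")

beverages = sum(r.is_beverage for r in db.records.values())
missing_fiber = sum(r.panel.fiber_g is None for r in db.records.values())
print(f"wrote {len(db)} records in {len(db.categories)} categories to {out}/")
print(f"beverages: {beverages}; records without declared fiber: {missing_fiber}")

# Same config + seed always reproduces the identical database, so fixtures
# never need to be stored - they are regenerated on demand.
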