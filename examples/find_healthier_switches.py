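"""Scan a barcode and list healthier same-category alternatives.

Generates a small synthetic database, prepares it (imputation + scoring +
labelling), then runs the scan flow in both ranking modes.
"""

from nutriswitch import (GeneratorConfig, ScoredDatabase, generate_database,
                         recommend, scan)

db = generate_database(GeneratorConfig(seed=11, n_categories=8,
                                       products_per_category=(10, 15)))
engine = ScoredDatabase.prepare(db)

# pick a mid-scoring bread-like product as the query
query_upc = max((u for u, r in engine.db.records.items()
                 if not r.is_beverage), key=lambda u: engine.scores[u].final_score)
outcome = scan(engine, query_upc)
print(f"scanned {query_upc}: score {outcome.score.final_score}, "
      f"lights {[c.value for c in outcome.label.colors.values()]}")
print("healthier alternatives (profile-score mode):")
for rec, score, label in outcome.switch.alternatives[:5]:
    print(f"  {rec.upc}  score {score.final_score:>3d}  {rec.name}")

salt = recommend(engine, query_upc, mode="salt", max_results=5)
print("lower-sodium alternatives (salt mode):")
for rec, score, label in salt.alternatives:
    print(f"  {rec.upc}  sodium {rec.panel.sodium_mg:7.1f} mg  {rec.name}")

# Alternatives always come from the query's own category, always have a
# strictly better key (lower score, or strictly less sodium in salt mode),
# and are sorted best-first. A sugar-sweetened soft drink would instead get
# the category's standard advisory message and no product list.
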