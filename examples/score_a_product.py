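"""Nutrient-profile score for a single product.

Shows the baseline points (energy, saturated fat, sugars, sodium), the
modifying points (fvnl V, protein P, fiber F) and the final score.
Lower scores mean healthier products.
"""

from nutriswitch import (Category, FoodDatabase, FoodRecord, FvnlComposition,
                         NutrientPanel, score_record)

categories = {"cereal": Category("cereal", "Breakfast cereal", is_beverage=False,
                                 fiber_possible=True, fvnl_possible=True,
                                 default_fvnl_pct=5.0)}
cereal = FoodRecord(
    upc="9300000000031", name="fruit & fibre flakes", brand="Example Foods",
    category_id="cereal", is_beverage=False,
    panel=NutrientPanel(energy_kj=1500, protein_g=10, total_fat_g=2,
                        saturated_fat_g=0.4, carbohydrate_g=70, sugars_g=22,
                        sodium_mg=400, fiber_g=9,
                        fvnl=FvnlComposition(10, 5, 85)),
)
db = FoodDatabase(records={cereal.upc: cereal}, categories=categories)

s = score_record(cereal, db)
print(f"scoring category : {int(s.npsc_category)}")
print(f"baseline points  : energy {s.baseline.energy}, satfat {s.baseline.saturated_fat}, "
      f"sugars {s.baseline.sugars}, sodium {s.baseline.sodium}  (total {s.baseline.total})")
print(f"modifying points : V {s.v_points}, P {s.p_points}, F {s.f_points}")
print(f"final score      : {s.final_score}")

# The final score is exactly baseline - V - P - F. High sugars and sodium
# drive the baseline up; the cereal claws points back through its protein
# and fiber. The fvnl share (10% + double-weighted 5% concentrated) is far
# below the 40% needed for any V points.
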