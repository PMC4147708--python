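"""Traffic-light label for a single product.

Builds one food record and prints its four signpost colours plus the
uncoloured energy figure.
"""

from nutriswitch import FoodRecord, NutrientPanel, label_record

muesli_bar = FoodRecord(
    upc="9300000000017", name="fruit muesli bar", brand="Example Foods",
    category_id="snack-bars", is_beverage=False,
    panel=NutrientPanel(energy_kj=1650, protein_g=7, total_fat_g=15,
                        saturated_fat_g=6.2, carbohydrate_g=60, sugars_g=28,
                        sodium_mg=90),
    serving_size_g=45.0,
)

label = label_record(muesli_bar)
for nutrient, color in label.colors.items():
    print(f"{nutrient.value:14s} {color.value}")
print(f"{'energy':14s} {label.energy_kj_display:.0f} kJ/100 g (no colour)")

# Total fat (15 g/100 g) and saturated fat (6.2 g) are in or above the
# "medium"/"high" bands; sugars at 28 g/100 g is "high" (red); salt from
# 90 mg sodium is 0.225 g/100 g, comfortably "low" (green). The 45 g serving
# is too small for any per-portion red override to fire.
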