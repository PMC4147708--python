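{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Food records table",
  "type": "object",
  "required": ["records"],
  "properties": {
    "records": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["upc", "name", "category_id", "is_beverage", "energy_kj",
                     "protein_g", "total_fat_g", "saturated_fat_g",
                     "carbohydrate_g", "sugars_g", "sodium_mg"],
        "properties": {
          "upc": {"type": "string", "pattern": "^[0-9]+$"},
          "name": {"type": "string"},
          "brand": {"type": "string"},
          "category_id": {"type": "string"},
          "is_beverage": {"type": ["boolean", "string"]},
          "serving_size_g": {"type": ["number", "string", "null"]},
          "energy_kj": {"type": ["number", "string"]},
          "protein_g": {"type": ["number", "string"]},
          "total_fat_g": {"type": ["number", "string"]},
          "saturated_fat_g": {"type": ["number", "string"]},
          "carbohydrate_g": {"type": ["number", "string"]},
          "sugars_g": {"type": ["number", "string"]},
          "sodium_mg": {"type": ["number", "string"]},
          "fiber_g": {"type": ["number", "string", "null"]},
          "calcium_mg": {"type": ["number", "string", "null"]},
          "pct_fvnl_nonconc": {"type": ["number", "string", "null"]},
          "pct_fvnl_conc": {"type": ["number", "string", "null"]},
          "pct_non_fvnl": {"type": ["number", "string", "null"]},
          "provenance": {"enum": ["surveyed", "crowdsourced"]}
        }
      }
    }
  }
}
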