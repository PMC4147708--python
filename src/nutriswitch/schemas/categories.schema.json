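{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Category table",
  "type": "object",
  "required": ["categories"],
  "properties": {
    "categories": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["category_id", "name", "is_beverage"],
        "properties": {
          "category_id": {"type": "string"},
          "name": {"type": "string"},
          "is_beverage": {"type": ["boolean", "string"]},
          "fiber_possible": {"type": ["boolean", "string"]},
          "fvnl_possible": {"type": ["boolean", "string"]},
          "default_fvnl_pct": {"type": ["number", "string", "null"]},
          "npsc_category3_member": {"type": ["boolean", "string"]},
          "is_cheese": {"type": ["boolean", "string"]},
          "switch_excluded": {"type": ["boolean", "string"]},
          "standard_message": {"type": ["string", "null"]}
        }
      }
    }
  }
}
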