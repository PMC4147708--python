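{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "CLI scan output",
  "type": "object",
  "oneOf": [
    {
      "required": ["upc", "label", "score", "switch"],
      "properties": {
        "upc": {"type": "string"},
        "label": {
          "type": "object",
          "required": ["colors", "energy_kj_display", "basis"],
          "properties": {
            "colors": {
              "type": "object",
              "required": ["total_fat", "saturated_fat", "sugars", "salt"],
              "additionalProperties": {"enum": ["green", "amber", "red"]}
            },
            "energy_kj_display": {"type": "number"},
            "basis": {"enum": ["per100g_food", "per100ml_drink"]},
            "portion_red_applied": {"type": "array", "items": {"type": "string"}}
          }
        },
        "score": {
          "type": "object",
          "required": ["npsc_category", "baseline_points", "v_points",
                       "p_points", "f_points", "final_score"],
          "properties": {
            "npsc_category": {"enum": [1, 2, 3]},
            "baseline_points": {
              "type": "object",
              "required": ["energy", "saturated_fat", "sugars", "sodium", "total"]
            },
            "v_points": {"enum": [0, 1, 2, 5, 8]},
            "p_points": {"type": "integer"},
            "f_points": {"type": "integer"},
            "final_score": {"type": "integer"},
            "imputed_inputs": {"type": "array", "items": {"type": "string"}}
          }
        },
        "switch": {
          "type": "object",
          "required": ["query_upc", "mode", "alternatives"],
          "properties": {
            "query_upc": {"type": "string"},
            "mode": {"enum": ["npsc", "salt"]},
            "standard_message": {"type": ["string", "null"]},
            "alternatives": {"type": "array"}
          }
        }
      }
    },
    {
      "required": ["crowdsource_prompt"],
      "properties": {
        "crowdsource_prompt": {
          "type": "object",
          "required": ["upc", "requested_photos"],
          "properties": {
            "upc": {"type": "string"},
            "requested_photos": {"type": "array", "items": {"type": "string"}}
          }
        }
      }
    }
  ]
}
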