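{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Cohort outcome report",
  "type": "object",
  "required": [
    "provenance",
    "n_users",
    "n_submitting",
    "completion_histogram",
    "treatment_rates",
    "followup_means",
    "paired_effects",
    "vs_start_counts",
    "vs_end_counts",
    "relapse",
    "followup_recovery"
  ],
  "properties": {
    "provenance": {
      "type": "object",
      "required": ["policy", "thresholds", "horizon"],
      "properties": {
        "policy": {
          "type": "object",
          "required": ["caseness_inclusive", "rci_inclusive"],
          "properties": {
            "caseness_inclusive": {"type": "boolean"},
            "rci_inclusive": {"type": "boolean"}
          }
        },
        "thresholds": {"type": "object"},
        "horizon": {"type": "integer", "minimum": 1}
      }
    },
    "n_users": {"type": "integer", "minimum": 0},
    "n_submitting": {"type": "integer", "minimum": 0},
    "completion_histogram": {"type": "object"},
    "treatment_rates": {
      "type": "object",
      "additionalProperties": {"$ref": "#/$defs/rate"}
    },
    "followup_means": {"type": "object"},
    "paired_effects": {"type": "object"},
    "vs_start_counts": {"type": "object"},
    "vs_end_counts": {"type": "object"},
    "relapse": {
      "type": "object",
      "additionalProperties": {"$ref": "#/$defs/rate"}
    },
    "followup_recovery": {"$ref": "#/$defs/rate"}
  },
  "$defs": {
    "rate": {
      "type": "object",
      "required": ["numerator", "denominator", "percent"],
      "properties": {
        "numerator": {"type": "integer", "minimum": 0},
        "denominator": {"type": "integer", "minimum": 0},
        "percent": {"type": ["integer", "null"]}
      }
    }
  }
}
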