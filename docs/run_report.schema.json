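{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "panrep run report",
  "type": "object",
  "required": ["version", "seed", "key_level", "samples", "diversity", "enrichment", "selectivity"],
  "additionalProperties": false,
  "properties": {
    "version": {"type": "string"},
    "seed": {"type": "integer"},
    "key_level": {"enum": ["full_aa", "cdr3_aa", "cdr3_nt"]},
    "samples": {
      "type": "object",
      "description": "sample id -> read-funnel counts; each stage count is <= the previous one",
      "additionalProperties": {
        "type": "object",
        "required": ["pairs", "merged", "length_ok", "quality_ok", "extracted", "complete"],
        "additionalProperties": false,
        "properties": {
          "pairs": {"type": "integer", "minimum": 0},
          "merged": {"type": "integer", "minimum": 0},
          "length_ok": {"type": "integer", "minimum": 0},
          "quality_ok": {"type": "integer", "minimum": 0},
          "extracted": {"type": "integer", "minimum": 0},
          "complete": {"type": "integer", "minimum": 0}
        }
      }
    },
    "diversity": {
      "type": "object",
      "description": "subtype -> round (string) -> summary statistics",
      "additionalProperties": {
        "type": "object",
        "additionalProperties": {
          "type": "object",
          "required": ["n", "s_obs", "percent_unique", "shannon_nats", "simpson", "d1", "d2"],
          "additionalProperties": false,
          "properties": {
            "n": {"type": "integer"},
            "s_obs": {"type": "integer"},
            "percent_unique": {"type": "number"},
            "shannon_nats": {"type": "number"},
            "simpson": {"type": "number"},
            "d1": {"type": "number"},
            "d2": {"type": "number"}
          }
        }
      }
    },
    "enrichment": {
      "type": "object",
      "description": "cell subtype -> screen summary",
      "additionalProperties": {
        "type": "object",
        "required": ["n_clones", "n_pass"],
        "additionalProperties": false,
        "properties": {
          "n_clones": {"type": "integer"},
          "n_pass": {"type": "integer"}
        }
      }
    },
    "selectivity": {
      "type": "object",
      "required": ["n_clones", "assigned_counts", "n_ambiguous"],
      "additionalProperties": false,
      "properties": {
        "n_clones": {"type": "integer"},
        "assigned_counts": {
          "type": "object",
          "additionalProperties": {"type": "integer"}
        },
        "n_ambiguous": {"type": "integer"}
      }
    }
  }
}
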