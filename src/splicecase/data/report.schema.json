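{
  "type": "object",
  "required": ["tool", "variant", "splice_consequence", "cpg_delta",
               "methylation", "editing", "expression", "provenance"],
  "properties": {
    "tool": {"type": "string"},
    "variant": {
      "type": "object",
      "required": ["contig", "pos", "ref", "alt"],
      "properties": {
        "contig": {"type": "string"},
        "pos": {"type": "integer"},
        "ref": {"type": "string"},
        "alt": {"type": "string"}
      }
    },
    "splice_consequence": {"type": "object", "required": ["status"]},
    "cpg_delta": {"type": "object", "required": ["status"]},
    "methylation": {"type": "object", "required": ["status"]},
    "editing": {"type": "object", "required": ["status"]},
    "expression": {"type": "object", "required": ["status"]},
    "provenance": {
      "type": "object",
      "required": ["tool_version", "catalog_hash", "input_digests"],
      "properties": {
        "tool_version": {"type": "string"},
        "catalog_hash": {"type": "string"},
        "input_digests": {"type": "object"}
      }
    }
  }
}
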