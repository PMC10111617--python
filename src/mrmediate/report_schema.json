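{
  "type": "object",
  "required": ["software", "seed", "config", "exposure", "mediators", "retained_mediators"],
  "properties": {
    "software": {
      "type": "object",
      "required": ["name", "version"],
      "properties": {
        "name": {"type": "string"},
        "version": {"type": "string"}
      }
    },
    "seed": {"type": "integer"},
    "config": {"type": "object"},
    "exposure": {
      "type": "object",
      "required": ["trait", "counts", "f_range", "estimates"],
      "properties": {
        "trait": {"type": "string"},
        "counts": {"type": "object"},
        "f_range": {"type": "array", "items": {"type": "number"}},
        "estimates": {"type": "object"}
      }
    },
    "exposure_label": {"type": "string"},
    "mediators": {"type": "object"},
    "retained_mediators": {"type": "array", "items": {"type": "string"}}
  }
}
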