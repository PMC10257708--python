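{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "brainprg full-analysis report",
  "type": "object",
  "required": ["config", "stages", "exponents", "seeds", "warnings"],
  "properties": {
    "config": {"type": "object"},
    "seeds": {"type": "object"},
    "warnings": {"type": "array"},
    "exponents": {
      "type": "object",
      "properties": {
        "eta": {"type": "number"},
        "alpha": {"type": "number"},
        "beta": {"type": "number"},
        "mu": {"type": "number"},
        "alpha_cb": {"type": "number"},
        "beta_cb": {"type": "number"},
        "mu_cb": {"type": "number"}
      }
    },
    "stages": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["status"],
        "properties": {
          "status": {"type": "string", "enum": ["ok", "failed", "skipped"]}
        }
      }
    }
  }
}
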