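{
  "title": "fcgnn connectome classification report",
  "required": {
    "version": {"type": "string"},
    "config": {"type": "object"},
    "seeds": {"type": "array"},
    "attribution": {
      "type": "object",
      "required": {
        "disorder_label": {"type": "string"},
        "k": {"type": "number"},
        "counts": {"type": "object"},
        "percentages": {"type": "object"}
      }
    },
    "correlations": {"type": "array"},
    "run_summary": {"type": "object"},
    "notes": {"type": "array"}
  }
}
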