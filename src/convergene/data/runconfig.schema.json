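{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "convergene run configuration",
  "type": "object",
  "required": ["gene_lists"],
  "properties": {
    "universe_size": {
      "type": "integer",
      "minimum": 1,
      "default": 19814,
      "description": "Number of genes N in the universe all overlap statistics condition on."
    },
    "gene_lists": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["name", "path", "role"],
        "properties": {
          "name": {"type": "string"},
          "path": {"type": "string", "description": "Gene list file, one symbol per line."},
          "role": {"enum": ["evolution", "expression", "phenotype", "tissue"]}
        }
      }
    },
    "annotations": {
      "type": "array",
      "items": {"type": "string"},
      "description": "Annotation files (two-column TSV or GMT) for the enrichment battery."
    },
    "reference_map": {
      "type": "object",
      "additionalProperties": {"type": "string"},
      "description": "Overlap-set name -> reference list name for enrichment."
    },
    "p_threshold": {"type": "number", "default": 0.05},
    "out_dir": {"type": "string", "default": "convergene-out"},
    "seed": {"type": "integer", "default": 0}
  }
}
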