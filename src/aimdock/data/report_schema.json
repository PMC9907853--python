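{
  "type": "object",
  "required": ["round_index", "pockets_sha", "candidates", "masked_loci"],
  "properties": {
    "round_index": {"type": "integer"},
    "pockets_sha": {"type": "string"},
    "models_dir": {"type": "string", "nullable": true},
    "masked_loci": {"type": "object"},
    "candidates": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["protein_id", "round", "status", "class", "models"],
        "properties": {
          "protein_id": {"type": "string"},
          "round": {"type": "integer"},
          "status": {"type": "string"},
          "w_pos": {"type": "integer", "nullable": true},
          "l_pos": {"type": "integer", "nullable": true},
          "core": {"type": "string", "nullable": true},
          "class": {"type": "string"},
          "separation": {"type": "integer", "nullable": true},
          "interface_plddt": {"type": "number", "nullable": true},
          "bin": {"type": "string"},
          "conserved_fraction": {"type": "number", "nullable": true},
          "disorder": {"type": "string", "nullable": true},
          "n_scan_hits": {"type": "integer"},
          "models": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["model_id", "docked", "motif_class"],
              "properties": {
                "model_id": {"type": "string"},
                "docked": {"type": "boolean"},
                "motif_class": {"type": "string"},
                "core": {"type": "string", "nullable": true},
                "interface_plddt": {"type": "number", "nullable": true},
                "confidence_bin": {"type": "string"},
                "reason": {"type": "string", "nullable": true}
              }
            }
          }
        }
      }
    }
  }
}
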