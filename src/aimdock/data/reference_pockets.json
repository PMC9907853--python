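{
  "receptor_id": "fixture_seed0_rank_001:A",
  "w_site": [
    27,
    28,
    29
  ],
  "l_site": [
    30,
    31,
    32
  ],
  "source": "reference-derived",
  "provenance": "derived from the bundled SYNTHETIC reference complex (fixtures.build_complex_model, seed 0) with the 5.0 A heavy-atom rule; regenerate with `aimdock pockets` against a real receptor-peptide structure"
}
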