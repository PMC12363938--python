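{
  "both": 0,
  "fraction_explained": 1.0,
  "leader_only": 16,
  "n_explained": 54,
  "n_genes": 54,
  "neither": 22,
  "orf_only": 16,
  "utr3_cutoff": 435.122707,
  "utr3_cutoff_flags": []
}
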