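optics:
  g_factor: 1.25
preprocess:
  background: 50.0
simulate:
  kinetics:
    k_ox: 0.011552453009332421   # ln2 / 60 s
    k_red: 0.0023104906018664843 # ln2 / 300 s
  imaging:
    seed: 1
io:
  output_dir: assay_out
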