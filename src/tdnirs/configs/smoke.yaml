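# Four-subject smoke configuration: full pipeline in ~1 minute.
seed: 20240901
design:
  n_norm: 1
  n_glaucoma: 1
  n_mixed: 2
stats:
  with_c_ci: false
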