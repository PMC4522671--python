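# Intermediate scenario: dispersal limitation plus moderate niche
# filtering (sigma_f of one field sd).
simulate:
  preset: mixed
  seed: 0
analysis:
  width: 100.0
  height: 100.0
  scales: [10.0, 20.0, 50.0]
  habitat_scale: 20.0
  n_null: 199
  n_perm: 199
  seed: 0
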