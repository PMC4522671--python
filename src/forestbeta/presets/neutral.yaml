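# Pure dispersal limitation on a 1-ha scaled plot: stems follow a Thomas
# cluster process and never interact with the environment.
simulate:
  preset: neutral
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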