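# Strong environmental filtering on a 1-ha scaled plot.
# Niche breadth sigma_f is narrow relative to the (unit-sd) soil filter
# field, and the filter field is coupled to topography so habitat types
# carry the filter.
simulate:
  preset: filtered
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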