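# Example file-based pipeline run: a scaled-down simulans-like experiment.
out_dir: scratch/example_run
species: simulans_like
normalization_set: conserved_1000
alpha: 0.1
span: 0.4
min_arrays: 2
simulation:
  n_features: 4000
  n_arrays: 6
  seed: 1
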