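# Scaled-down study configuration for `mosr-study run`.
dataset_arms: [clinical, crf, combined]
model_arms: [mosr, lr, scores]
generator:
  n_patients: 500
  seed: 1
evolution:
  population_size: 60
  generations: 40
  seed: 0
grids:
  lr:
    - {C: 1.0}
cv_folds: 3
n_test_runs: 5
master_seed: 7
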