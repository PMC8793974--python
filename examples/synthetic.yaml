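# End-to-end example on synthetic data shaped like the Cleveland table
# (n=297, ~46/54 class split, 5 continuous + 8 categorical predictors).
# Sized to run in minutes on one CPU: 25 MCCV iterations at two ratios
# with fixed hyperparameters; raise n_iter and switch tune_mode to
# "nested" for a full protocol run.
synthetic:
  n: 297
  cleveland_like: true
  seed: 11
weights_mode: per-split
standardize: true
tune_mode: fixed
C: 2.0
gamma: 0.5
ratios: [0.80, 0.50]
n_iter: 25
master_seed: 2021
methods: [wsvm, svm, rf, nb]
out_dir: results/example
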