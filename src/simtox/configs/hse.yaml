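# Heat-shock element (HSE) stress-response endpoint preset:
# RF with information-gain-ratio splits and 0.7 bootstrap fraction; 3NN.
target_name: HSE
fp_type: MACCS
with_descriptors: false
method:
  algo: rf
  split_criterion: info_gain_ratio
  data_fraction: 0.7
  n_trees: 1000
  seed: 0
knn_k: 3
cv:
  folds: 13
  seed: 0
paths:
  input: null
  format: smiles
  outdir: runs/hse
synth:
  n_train: 1300
  n_external: 647
  active_fraction: 0.03
  n_bits: 166
  template_distance: 40
  flip_prob: 0.1
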