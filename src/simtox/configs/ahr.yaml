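# Aryl hydrocarbon receptor (AhR) endpoint preset:
# RF with Gini splits and 0.8 bootstrap fraction; 5NN similarity search.
target_name: AhR
fp_type: MACCS
with_descriptors: false
method:
  algo: rf
  split_criterion: gini
  data_fraction: 0.8
  n_trees: 1000
  seed: 0
knn_k: 5
cv:
  folds: 13
  seed: 0
paths:
  input: null        # when null, a synthetic dataset is simulated
  format: smiles
  outdir: runs/ahr
synth:
  n_train: 1300
  n_external: 647
  active_fraction: 0.03
  n_bits: 166
  template_distance: 40
  flip_prob: 0.1
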