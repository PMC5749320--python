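# Desk-scale end-to-end run: margincnn run-all --config docs/example_config.yaml
out_dir: scratch/example_run
master_seed: 7
train_cohort: {tag: A, n_adenoma: 12, n_carcinoma: 12}
test_cohorts:
  - {tag: B, n_adenoma: 4, n_carcinoma: 4}
patch_size: 50
patches_per_nodule: 5
min_spacing: 8
channel_scale: 16
epochs: 30
batch_size: 16
learning_rate: 0.001
n_restarts: 3
cohort_alpha: {B: -0.75}
tie_rule: carcinoma
sweep_grid: [-1.5, -0.75, 0.0, 0.75, 1.5]
roc_grid: [-0.6, -0.3, 0.0, 0.3, 0.6]
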