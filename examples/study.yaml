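# Desk-scale ablation study: synthetic planted-motif benchmark,
# 4-layer tiny encoder, 3 seeds per condition.
schema_version: 1
output_dir: out
seeds: [0, 1, 2]
dataset:
  synthetic:
    n_train: 2000
    n_val: 200
    n_test: 400
    L: 64
    seed: 0
model:
  tiny:
    n_layers: 4
    d_model: 32
    n_heads: 4
    d_ff: 64
    max_len: 128
    seed: 0
pretrain:
  mode: to_convergence
  max_epochs: 50
  patience: 5
finetune:
  mode: fixed_epochs
  fixed_epochs: 3
classification:
  min_criteria: 3
  cornerstone_drop: 0.05
  drop_mode: relative
  tolerance_source: layer_sd
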