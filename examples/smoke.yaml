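# Scaled-down end-to-end experiment: 8 participants, 2 experimental days,
# 2-min drives, 512-sample windows. Finishes in a few minutes on one CPU.
seed: 11
out_dir: scratch/smoke-run
tasks: [sitting_history, sleep_history]
architectures: [dixonnet]

cohort:
  cell_counts:
    sitting: {sleep_9h: 2, sleep_5h: 2}
    breaking_up_sitting: {sleep_9h: 2, sleep_5h: 2}
  effect_size_activity: 3.0
  effect_size_sleep: 3.0
  drive_duration: 120.0
  days: 2

dataset:
  window_length: 512
  eval_stride: 256
  split_mode: window_level
  k: 2

training:
  max_epochs: 10
  windows_per_epoch: 192
  initial_lr: 1.0e-3

cam:
  n_exemplars: 2
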