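# Desk-scale profile: every stage runs in minutes on one CPU.
#
# All constants the underlying study leaves unstated appear here with the
# package defaults; paper-scale settings (96^3 pretraining crops, 16^3
# patches, 1x1x2 mm working spacing, masking ratio 0.7) are documented in
# docs/methods.md — the desk-scale segmentation decoder is fixed to 8^3
# patches, so the larger patch size applies to pretraining only.

seed: 1
k_folds: 5

phantom:
  n_subjects: 12
  shape: [64, 64, 96]
  spacing: [1.5, 1.5, 2.0]
  prevalence: 0.14
  variability: 0.08

pretrain:
  epochs: 5
  crop: 32
  patch_size: 8
  d: 64
  depth: 4
  heads: 4
  mask_ratio: 0.7   # fraction of patches masked
  bias_eta: 0.5     # bone-bias strength in w_i = 1 - eta * b_i
  crops_per_volume: 2
  lr: 0.001

segment:
  epochs: 2
  steps_per_epoch: 4
  crop: 48
  # random_init: true   # skip the pretrained encoder

classify:
  epochs: 60
  message_passing: false   # optional chain message-passing step
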