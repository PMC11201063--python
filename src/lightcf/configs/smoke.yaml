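# CPU smoke-scale profile: tiny fixtures, few optimiser steps, no augmentation.
model:
  variant: baseline
  stage_channels: [16, 32, 64, 128, 128]
  decoder_channels: [64, 64, 32, 16]
train:
  init_lr: 0.001
  power: 0.9
  max_epoch: 200
  batch_size: 8
  weight_decay: 1.0e-5
  augment: false
  max_steps: 200
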