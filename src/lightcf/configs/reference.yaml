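# Calibrated full-network configuration (ablation Table parameter budget).
model:
  variant: full
  stage_channels: [16, 32, 64, 128, 128]
  decoder_channels: [64, 64, 32, 16]
  ca_reduction: 4
  lka: {dw_kernel: 5, dwd_kernel: 7, dwd_dilation: 3}
  vam_expansion: 2.0
  vam_state_dim: 16
  vam_conv_kernel: 4
  vam_dt_rank: null          # ceil(C / 16) per skip level
  vam_levels: [0, 1, 2, 3]
  psa: {splits: 4, branch_input: full, groups: [1, 4, 8, 16], se_reduction: 4}
  out_channels: 1
train:
  init_lr: 0.001
  power: 0.9
  max_epoch: 200
  batch_size: 8
  weight_decay: 1.0e-5
  augment: true
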