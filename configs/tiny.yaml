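# Desk-scale profile: trains in minutes on one CPU core.
model:
  scale: 2
  in_channels: 1
  embed_dim: 32
  num_atbs: 2
  stls_per_atb: 2
  window_size: 8
  num_heads: 4
  mlp_ratio: 2.0
  use_rel_bias: true
train:
  initial_lr: 2.0e-4
  lr_decay_per_update: 0.999
  batch_size: 8
  total_updates: 2000
  loss_kind: l1
phantom:
  size: 128
  n_organs: 4
  noise_sd: 0.01
  texture_amplitude: 0.03
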