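# Desk-scale run configuration: reduced decoder + short-budget regimen
# for CPU experiments on synthetic data. Omitted keys keep the published
# full-scale defaults.
model:
  conv_out_channels: [8, 16, 16, 16]
  pool_size: 3
  lstm_hidden: 16
  lstm_layers: 1
  patch_size: 4
  stride: 2
  embed_dim: 32
  tf_layers: 1
  n_heads: 2
  conv_dropout: 0.1
  lstm_dropout: 0.1
  tf_dropout: 0.1
train:
  lr: 2.0e-3
  warmup_epochs: 3
  batch_size: 16
  max_epochs: 30
meta:
  inner_lr: 0.05
  second_order: false
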