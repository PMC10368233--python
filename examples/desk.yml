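# Desk-scale run configuration: window/step and network scaled down from the
# reference 10-kb settings (250/50, H=128, B=40) to train in minutes on CPU.
window: 64
step: 16
band_min_bins: 2
band_max_bins: 48
channel_mode: both
model:
  hidden_dim: 16
  n_blocks: 4
train:
  batch_size: 4
  lr: 0.01
  max_epochs: 60
  seed: 0
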