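# Cytosolic -> nuclear-localized GCaMP translation (zebrafish calcium imaging).
name: calcium
patch_size: 256
norm_mode: percentile_scale   # scale by the 99th percentile
norm_lo: 0.0
norm_hi: 99.0
levels: [8, 16, 32]
feature_channels: 8
in_channels_a: 1
in_channels_b: 1
use_batchnorm: false          # omitted for calcium's broad dynamic range
use_modulation: true
upsampler: dynamic
use_info_loss: true
final_activation: none
lambda_adv: 1.0
lambda_cyc: 5.0
lambda_info: 10.0
schedule_enabled: true
schedule_steepness: 10.0
schedule_midpoint: 0.5
iterations: 100000
learning_rate: 0.0003
disc_channels: [64, 128, 256, 512]
augment: true
checkpoint_every: 1000
seed: 0
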