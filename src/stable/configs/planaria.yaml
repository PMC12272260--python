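# Low-SNR -> high-SNR fluorescence restoration (planaria volumes, 64 px z-slices).
name: planaria
patch_size: 64
norm_mode: percentile
norm_lo: 0.1
norm_hi: 99.9
levels: [32, 64, 128, 256]
feature_channels: 3
in_channels_a: 1
in_channels_b: 1
use_batchnorm: true
use_modulation: true
upsampler: dynamic
use_info_loss: true
final_activation: none
lambda_adv: 1.0
lambda_cyc: 10.0
lambda_info: 1.0
schedule_enabled: false
schedule_steepness: 10.0
schedule_midpoint: 0.5
iterations: 100000
learning_rate: 0.0003
disc_channels: [64, 128, 256, 512]
augment: true
checkpoint_every: 1000
seed: 0
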