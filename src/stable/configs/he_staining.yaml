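# Two-photon fluorescence -> virtual H&E staining.
name: he_staining
patch_size: 512
norm_mode: range01
norm_lo: 0.0
norm_hi: 100.0
levels: [32, 64, 128, 256]
feature_channels: 3
in_channels_a: 1              # fluorescence
in_channels_b: 3              # H&E RGB
use_batchnorm: true
use_modulation: true
upsampler: dynamic
use_info_loss: true
final_activation: sigmoid     # outputs bounded to [0, 1]
lambda_adv: 5.0
lambda_cyc: 10.0
lambda_info: 10.0
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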