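# Desk-scale rings->disks task (synthetic cytosolic vs nuclear GCaMP).
name: synthetic
patch_size: 64
norm_mode: percentile
norm_lo: 0.1
norm_hi: 99.9
levels: [8, 16, 32]
feature_channels: 8
in_channels_a: 1
in_channels_b: 1
use_batchnorm: false
use_modulation: true
upsampler: dynamic
use_info_loss: true
final_activation: none
lambda_adv: 1.0
lambda_cyc: 5.0
lambda_info: 10.0
schedule_enabled: false
schedule_steepness: 10.0
schedule_midpoint: 0.5
iterations: 500
learning_rate: 0.0003
disc_channels: [16, 32, 64]
augment: true
checkpoint_every: 100
seed: 0
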