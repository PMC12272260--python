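# stable-translate

Unpaired biomedical image-to-image translation that preserves **spatial** and
**quantitative** information.

Many biomedical questions need the same sample seen through two modalities —
cytosolic vs. nuclear-localized calcium indicators, label-free microscopy vs.
histological staining, T2- vs. PD-weighted MRI — but paired acquisitions are
usually impossible. Cycle-consistent GANs (CycleGAN and descendants) learn
such mappings from *unpaired* sets, yet cycle consistency only guarantees that
a translation is *invertible*, not that it is *accurate*: a model can shift a
neuron's nucleus to the rim of its soma, or invert foreground and background,
and still reconstruct the input perfectly. For quantitative biology — counting
cells, localizing nuclei, reading out activity traces — that failure mode is
disqualifying.

This package implements a translation framework with two additions that
target pixel-level fidelity:

1. **Information consistency on full-resolution features.** Each generator is
   an encoder–decoder pair. Encoders `G_A`, `G_B` map images into a shared
   feature domain at the *same spatial resolution* as the input,
   `Z_A = G_A(X_A) ∈ R^{C_Z×H×W}`, and decoders translate,
   `X_{A→B} = F_B(Z_A)`. Alongside the usual LSGAN adversarial loss and the
   L1 cycle loss

       L_cyc = |X_A − T_{B→A}(T_{A→B}(X_A))|₁ + |X_B − T_{A→B}(T_{B→A}(X_B))|₁,

   training penalizes disagreement between the features of an input and the
   features re-encoded from its translation:

       L_info = |Z_A − G_B(X_{A→B})|₁ + |Z_B − G_A(X_{B→A})|₁,

   with total objective `L_tot = λ_adv·L_adv + λ_cyc·L_cyc + λ_info·L_info`.

2. **Learnable dynamic upsampling.** Inside the U-shaped encoders/decoders,
   fixed bilinear upsampling is replaced by an operator that *learns where to
   sample*: a 1×1 convolution predicts offsets `O_θ = Conv2D(X; θ)`
   (shape `2s²×H×W`), pixel shuffle rearranges them to `2×sH×sW`, and the
   feature map is bilinearly resampled at `S = G + O`, the uniform grid plus
   the learned offsets. Zero-initialized offsets make the operator start as
   exact bilinear interpolation.

Because GPU-scale GANs and the original datasets are impractical on a
workstation, the package ships a first-class **synthetic two-domain
microscopy generator** that reproduces the statistical structure of the
cytosolic→nuclear calcium translation task: shared latent cell positions and
activity traces, rendered as cytosolic rings (domain A) vs. nuclear disks
(domain B), anti-monotonic at the pixel level inside cells and exactly
positively correlated at the cell level. Everything — training, evaluation,
ROI correspondence, ΔF/F traces — is testable at desk scale on one CPU.

The neural-network machinery (reverse-mode autodiff, convolution, pooling,
differentiable grid sampling, batch norm, AdamW) is implemented in numpy
inside the package (`stable._tensor`, `stable.nn`), sized for these
desk-scale experiments.

## Worked example

```python
import numpy as np
from stable.synthetic import make_dataset
from stable.training import TaskConfig, train, build_models
from stable.evaluation import evaluate_paired_translation

ds = make_dataset(seed=1)                    # 40 ring + 40 disk images, 64x64
cfg = TaskConfig.from_name("synthetic")      # lambdas (1, 5, 10), AdamW 3e-4
cfg.seed = 1
res = train(cfg, ds.train_a, ds.train_b)     # 500 iterations, ~2 min on CPU

print(f"generator loss: {np.median([r['loss_gen_total'] for r in res.log[:50]]):.2f}"
      f" -> {np.median([r['loss_gen_total'] for r in res.log[-50:]]):.2f}")
ev = evaluate_paired_translation(res.generators, ds, cfg)
print(ev)
```

Output from this exact run:

```
generator loss: 1.82 -> 1.21
{'median_centroid_distance': 2.744, 'median_iou': 0.107,
 'median_trace_pcc': 0.875, 'n_rois_reference': 28, 'n_rois_translated': 29}
```

Reading: after training, nuclei segmented from the translated images sit a
median 2.7 px from the true nucleus centers (soma radius is 8 px; an
untrained model gives ~12.9 px), the translated ROI count (29) matches the 28
true nuclei, and per-ROI activity traces extracted from the translations
correlate with the latent ground-truth traces at a median Pearson r of 0.87 —
spatial position, cell count and signal dynamics survive the translation.
Disabling the information-consistency term roughly doubles the centroid
error (5.3 px) under identical conditions.

## Command line

```bash
stable simulate --seed 1 --out data/            # synthetic two-domain dataset
stable train --config src/stable/configs/synthetic.yaml \
             --data-a data/train_A --data-b data/train_B --out run/
stable translate --checkpoint run/checkpoints/best.npz \
                 --input data/test/pair_000/stack_A.tif --out pred/
stable evaluate --input pred/translated.tif \
                --reference data/test/pair_000/stack_B.tif --out report/
```

Large frames are translated tile-by-tile with 25 % overlap and linear
feathering. Shipped configs under `src/stable/configs/` reproduce the
published hyperparameters for the calcium, H&E-staining, DAPI-labeling, MRI
and denoising tasks (loss weights, channel widths, feature channels,
normalization percentiles, batch-norm toggles); training them at full scale
requires the corresponding datasets and far more compute than the synthetic
task.

Note on ROI masks: instance segmentation of real data (e.g. Cellpose) is out
of scope; the evaluation module *consumes* integer label masks and provides
`segment_blobs` (Otsu + connected components) as a desk-scale stand-in.

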