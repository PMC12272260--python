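# Methods

## Model

Two image domains A and B are linked by translation generators implemented as
encoder–decoder pairs: `T_{A→B} = F_B ∘ G_A` and `T_{B→A} = F_A ∘ G_B`. The
encoders map a `C×H×W` image to a feature map with `C_Z` channels at the
**same** spatial size; the feature domain is shared between the two domains
and is where the information-consistency constraint acts. Patch-based
least-squares (LSGAN) discriminators `D_A`, `D_B` score realism.

The objective is `L_tot = λ_adv·L_adv + λ_cyc·L_cyc + λ_info·L_info` with

- `L_adv` in least-squares form: discriminator term
  `½·mean[(D(real)−1)²] + ½·mean[D(fake)²]` per domain (fakes detached),
  generator term `½·mean[(D(fake)−1)²]` per domain. A logistic
  (cross-entropy) form is available behind `form="logistic"`; the
  least-squares form is the one used by every shipped config.
- `L_cyc`: mean absolute error of the A→B→A and B→A→B reconstructions.
- `L_info`: mean absolute error between the features of an input and the
  features re-encoded from its translation,
  `|Z_A − G_B(X_{A→B})|₁ + |Z_B − G_A(X_{B→A})|₁`.

All L1 terms are **means** over elements rather than sums, so λ values are
comparable across patch sizes and channel counts.

**Gradient treatment of `L_info`.** The constraint's value is symmetric, but
backpropagating through both arguments gives the optimizer a degenerate
descent direction: both encoders can collapse onto a constant feature map,
zeroing `L_info` while destroying the features the decoders need. At desk
scale this collapse is reliable and fast (feature std → ~0.005 within tens of
iterations) and survives weight demodulation, because dead-ReLU channels can
carry it. We therefore treat the plain encodings `Z_A`, `Z_B` as *detached
consistency targets*, the standard convention in consistency-regularized
training: the re-encoded features are pulled toward them, and the encoders
receive their `L_info` gradient only through the translation path. The loss
value is identical; only the gradient path differs. With this treatment the
desk-scale experiment trains cleanly (see "What passing tests show" below).

## Architecture

Encoders and decoders share one U-shaped template: a contracting path of
blocks (two 3×3 convolutions, each followed by optional batch norm and ReLU)
with 2×2 max pooling between levels, and an expansive path that upsamples by
2, concatenates the skip features and applies another block; a final 1×1
convolution produces the `C_Z` feature channels (encoder) or output image
channels (decoder, optionally sigmoid-bounded for [0,1] tasks). Inputs whose
sides are not divisible by `2^(levels−1)` are reflect-padded and cropped back.

**Dynamic upsampling.** The expansive-path upsampler predicts a displacement
for every output pixel: a 1×1 convolution on the low-resolution feature map
produces `2s²` channels, pixel shuffle rearranges them into a `2×sH×sW`
offset grid `O`, and the feature map is bilinearly resampled at `S = G + O`
where `G` is the uniform pixel-center grid (output pixel `(u,v)` ↦ input
coordinate `((v+0.5)/s − 0.5, (u+0.5)/s − 0.5)`, 0-based, x = column).
Coordinates are clamped to the border before interpolation. The offset head
is zero-initialized, so at initialization the operator *is* bilinear
interpolation and training can only improve on that baseline. An optional
scalar offset multiplier exists (default 1.0). A fixed `BilinearUpsample` is
available as the ablation alternative (`upsampler: bilinear`).

**Weight modulation/demodulation.** `modulate_demodulate(W, s)` multiplies
weights per input channel by `s` and renormalizes each output filter to unit
L2 norm (+ε); uniform rescaling of `s` cancels exactly. When enabled, all
3×3 block convolutions *and* the 1×1 heads use it, with per-layer learned
scale vectors (self-modulation — the conditioning signal is an open design
choice; nothing in the training recipe provides a style input). Two
consequences at implementation level: (i) unit-norm filters halve ReLU
activation variance per layer, which would let a ~12-conv U-Net decay its
output to the bias field at init, so a fixed He-style √2 gain follows
demodulation; (ii) demodulated heads cannot shrink their weights to zero,
which removes one route to feature collapse.

**Discriminators.** Stacked 4×4 stride-2 convolutions (widths 64/128/256/512
for the full-scale configs, 16/32/64 for the desk-scale config), batch norm
after every strided conv except the first, LeakyReLU(0.2), and a final 3×3
convolution to a single-channel unbounded score map.

## Training

One iteration: sample one random patch per domain (uniform frame + corner,
per-frame percentile normalization computed on full frames before patching),
optionally augment (random 90° rotations, independent H/V flips), update the
discriminators (on detached translations), then the generators, each once,
with AdamW (lr 3·10⁻⁴, no weight decay, batch size 1). The cycle weight can
follow a sigmoid schedule `λ_cyc·σ(k·(i/I − m))` (defaults k = 10, m = 0.5);
it is enabled only for the calcium config, the one task whose recipe calls
for it. The desk-scale synthetic config keeps it off — with the schedule on,
the growing weight inflates the late-training total loss and masks learning
progress. The global seed splits into independent streams (initialization,
patch sampling, augmentation), so runs are bit-reproducible in
single-threaded numpy and toggling augmentation does not shift
initialization. A non-finite loss aborts with a diagnostic snapshot.
Checkpoints (all parameters + the config that built them) are written
periodically; the last three and the best-by-generator-loss are kept.

Per-task configs ship in `src/stable/configs/` (loss weights, channel
widths, `C_Z`, normalization, batch-norm toggle per task). Iteration counts
for the full-scale tasks are config fields with nominal defaults (100 000);
the desk-scale synthetic task uses 500 iterations, chosen as the package's
standard desk experiment (~2 min on one CPU core).

## Synthetic data generator

The generator emulates the two-domain calcium-imaging structure:

- **Latent field**: `n` cells (default 7) at pixel-grid positions with
  pairwise separation ≥ 2·r_cyto (defaults r_cyto = 8 px, r_nuc = 4 px at
  64×64 — half-scale somata of ~16 px diameter). Packing infeasibility is an
  explicit error, detected up front by a random-packing area bound
  (n·π·(sep/2)² > 0.6·H·W, motivated by random-sequential-adsorption
  saturation ≈ 0.55) or after bounded rejection attempts.
- **Traces**: per-cell Poisson spike trains (default 0.05 events/frame)
  convolved with an exponential kernel (τ = 8 frames), plus a per-cell
  constant baseline (0.3 ± 30 %), mimicking heterogeneous indicator
  expression; nonnegative by construction.
- **Rendering**: smooth logistic radial profiles (edge width 1 px) rather
  than hard edges, so the GAN task is not artificially easy. Domain A is a
  soft annulus with its center dimmed to 20 % of the rim; domain B a soft
  disk of radius r_nuc; both scale with a_i(t) over a constant background
  (0.1). Gaussian noise (σ = 0.05 of unit range) is added last; Poisson shot
  noise is available but off by default; output clipped to ≥ 0.
- **Masks**: the domain-A label footprint is the *filled* soma disk (what an
  instance segmenter returns for ring-shaped somata), domain B the nuclear
  disk; overlapping pixels go to the nearer center. Hence nuclear ⊂ soma and
  IoU(nuc, soma) = (r_nuc/r_cyto)² = 0.25 analytically.
- **Splits**: every training image has its own cell field; A-side and B-side
  field seeds are disjoint, so the training set is unpaired *by
  construction*. Test samples are paired (one shared field per pair) with
  masks and latent traces.

Pixel-grid centers make every cell's rasterized footprint identical, so the
cell-level mean-intensity relationship between noiseless A and B renders is
exactly affine in a_i(t); the measured Pearson correlation is 1 up to the
logistic profile tails of neighboring cells (deviation < 10⁻³). Inside a
cell the radial intensity profiles of A and B have exactly reversed rank
order (Spearman ρ ≈ −1): the anti-monotonic pixel-level relationship.

**What the generator does not emulate**: sub-pixel cell positions, optics
beyond the soft edge profile (no PSF convolution), motion, occlusion and 3D
structure, photobleaching, and correlated background fluctuations (a
background-correlation knob exists for the latter). Passing desk-scale tests
therefore demonstrates that the method's machinery behaves as designed on
data with the assumed two-level intensity structure — not that it reaches
published-scale performance on real recordings.

## Evaluation

- `image_metrics`: RMSE, MAE, PSNR = 10·log₁₀(max(x)²/RMSE²) with `x` the
  first argument (so PSNR/SSIM are referenced, RMSE/MAE symmetric; identical
  images report +∞), global-statistics SSIM with C1 = (0.01·L)²,
  C2 = (0.03·L)², L the joint data range (a windowed variant is behind a
  flag for cross-tool comparability), and Pearson correlation (zero-variance
  inputs → NaN sentinel, no exception).
- ROI correspondence: unweighted per-label centroids; one-directional
  nearest-centroid matching (reference → translated, reuse allowed — no
  bipartite assignment); per-pair L2 centroid distance and single-ROI binary
  IoU; ROI counts per mask.
- Traces: per-ROI mean intensity per frame; ΔF/F against a trailing
  moving-average baseline of window k (shrinking window for the first k−1
  samples, window length is a config parameter tied to the recording rate).
  The conventional sign (p − MA)/MA is the default with an `invert_sign`
  flag, since the two sign conventions both appear in practice.
- `segment_blobs` (Otsu threshold + connected components, minimum area 5 px)
  stands in for a trained instance segmenter at desk scale.
- `evaluate_paired_translation` translates each paired test stack, segments
  the time-averaged translated image, scores it against the ground-truth
  nuclear masks, and correlates per-ROI traces extracted from the translated
  stack with the latent ground-truth traces. An empty segmentation reports
  the image diagonal as the distance sentinel.

## Inference on large frames

Frames larger than the training patch are translated in tiles with 25 %
overlap and linear feathering. Tiling is exact only beyond the network's
receptive field from any tile edge (measured influence radius ≈ 10 px per
2-level U-Net, ≈ 25 px per 3-level U-Net at 64×64); batch-norm configs use
global spatial statistics, so their tiled and untiled outputs agree only
approximately near seams. This is inherent to tiled inference of networks
with non-local components, not a defect of the blending.

## Numerical choices

- float32 throughout training; float64 in tests' finite-difference oracles.
- Grid sampling clamps out-of-range coordinates to the border; clamped
  positions get zero positional gradient.
- Batch norm with batch size 1 reduces to per-channel spatial (instance)
  statistics; ε = 10⁻⁵.
- Demodulation ε = 10⁻⁸; percentile normalization maps constant images to
  zero instead of dividing by zero; ΔF/F masks nonpositive baselines to NaN.
- Max pooling breaks ties by first occurrence (argmax convention).
- The numpy autodiff engine is single-threaded and deterministic; identical
  seeds give bit-identical loss logs and datasets.

## Known limitations

- The engine is CPU/numpy; full-scale configs (512×512, widths 256) run but
  are orders of magnitude slower than a GPU implementation — they are
  shipped for completeness of the recipes, not for routine training here.
- 500 desk-scale iterations show the method's *direction* (information
  consistency improving nuclear localization); absolute metric values at
  this scale have run-to-run spread across seeds.
- Only 2D per-slice processing; volumes are handled as slice stacks.
- No identity-mapping or perceptual losses; no gradient penalties; update
  ratio fixed at 1:1 — deliberately outside scope.
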