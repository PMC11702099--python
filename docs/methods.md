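# Methods

## Model

The translator is a conditional GAN for registered pairs (x, y): an H&E
patch x, its IHC counterpart y, and a HER2 level in {0, 1+, 2+, 3+}.

**Generator.** Two coupled encoder–transformer–decoder paths:

- *Full path* (256×256 default): 7×7 stem convolution, then three 3×3
  stride-2 convolutions, each followed by instance normalization and leaky
  ReLU (slope 0.2), producing a 1/8-scale feature map (32×32 at side 256).
- *Low path*: the input is bilinearly downsampled 4× (to 64×64), passed
  through the *same* stem and first downsample (shared storage, counted
  once) plus one private downsample, giving a 1/16-scale map (16×16).
- *Fusion*: the low path's transformer output and the classifier's
  stride-8/stride-16 feature taps are bilinearly upsampled to the full
  path's 1/8 scale, concatenated channel-wise with the full encoder output,
  and projected back to the transformer width by a 1×1 convolution.
  Classifier taps are gradient-detached: the classifier is trained first
  and acts as a frozen guidance network.
- *Transformers*: inverted-residual blocks (1×1 expansion → 3×3 depthwise
  → 1×1 projection, instance-normalized, residual add) — three blocks on
  the full path, one on the low path.
- *Decoders*: stride-2 3×3 transposed convolutions whose normalization is
  AdaIN — spatial standardization followed by a per-channel scale and
  shift produced from the HER2 level by a learned embedding and a 2-layer
  MLP (γ is parameterized as 1 + Δγ so conditioning starts near identity);
  a final 7×7 convolution and tanh bound outputs to [−1, 1].  The full
  decoder has three upsampling stages; the low decoder needs **two**
  (16→32→64): a single stage cannot return a 1/16-scale map to the low
  output resolution, so shape arithmetic fixes the depth.

**Discriminators.** Three PatchGANs without weight sharing, applied to the
channel-concatenated (x, y-or-fake) pair at full, 1/2 and 1/4 resolution
(3×3 stride-2 average pooling between scales).  Each scale: four 4×4
stride-2 convolutions with widths 64, 128, 256, 512, instance norm (no
affine) + leaky ReLU after all but the first, then a stride-1 4×4
convolution to a 1-channel patch-logit map.  The four body activations
plus the logits are the L = 5 feature taps per scale.

**Classifier.** A MobileNetV3-style stack (3×3 stride-2 stem, six
inverted-residual bottlenecks with squeeze-excitation and hard-swish,
1×1 head convolution, global average pooling, two fully-connected layers)
scoring the H&E patch into the four HER2 levels.  It uses *batch*
normalization, the backbone's native norm: instance norm would remove the
per-channel means that carry global stain density and tint — precisely the
class signal — and empirically leaves the classifier at chance on the
synthetic task.  Convolutions are He-initialized.  Feature taps are taken
after the last stride-8 and stride-16 blocks (tap layers are not pinned by
the backbone's published description; this is a documented choice).

## Objective

With raw logits l and σ the logistic function, the discriminator minimizes
−(E[log σ(l_real)] + E[log(1 − σ(l_fake))]) and the generator the
non-saturating −E[log σ(l_fake)], averaged over patch positions and the
three scales; a least-squares variant is available behind a flag.  The
same discriminators also score the low-resolution pair, bilinearly
upsampled to the full side, and the two adversarial terms are averaged.

Feature matching compares discriminator taps of real and generated pairs:
per layer the L1 distance divided by the layer's element count, averaged
over the L layers and three scales, once for the full-resolution pair and
once for the low-resolution pair (the two expectations add).  The
layer-averaged (rather than layer-summed) form keeps the loss scale
independent of discriminator depth.

The perceptual loss sums element-normalized L1 distances over the layers
of a feature extractor.  The default extractor is a fixed, seeded,
random-weight convolutional pyramid (stride-2 3×3 convolutions, widths
16/32/64/128, leaky ReLU): random deep features are a recognized basis
for perceptual distances and make the loss fully reproducible offline;
any callable returning per-layer feature tensors can be substituted.

Total: `L = λ_GAN·L_GAN + λ_VGG·L_VGG + λ_FM·L_FM + λ_L1·L_L1` with
defaults λ_GAN = 1, λ_FM = λ_VGG = 10, λ_L1 = 100 (the conventional
weighting for this family of translation models; all config-exposed).

## Training

Adam for both networks, lr 2·10⁻⁴, β = (0.5, 0.999); one discriminator
step (fakes detached) then one generator step per batch; batch size 4;
200 epochs at full scale.  Global seeding covers weight initialization,
shuffling and augmentation draws; repeated runs are bitwise-identical.
Per-epoch validation logs generator/discriminator losses plus raw-8-bit
PSNR and SSIM of G(x) against y to a CSV curve file; `latest` and `best`
(by validation PSNR) checkpoints bundle generator, discriminator and
classifier weights.

## Data handling

Images are RGB, row-major, origin top-left, channel-last on disk and in
the I/O layer (NCHW inside the networks), with an explicit range tag:
`raw8` ([0, 255]) or `norm` ([−1, 1], v ↦ v/127.5 − 1).  Resizing is
bilinear, anti-aliased when downscaling.  Augmentation draws one of the 12
rotation/flip transforms and applies it identically to both members of a
pair, preserving registration.  Splits are stratified per HER2 level:
validation and test take ⌊n·fraction⌋ pairs per level, training the
remainder, so partitions are disjoint and exhaustive.  (The published
split counts for the real dataset are internally inconsistent with its
stated total, so exact stratified fractions are implemented instead of
the printed counts.)

## Synthetic paired-stain task

The synthetic generator emulates a registered H&E/IHC patch-pair corpus:

- A seeded Gaussian-smoothed noise field is thresholded at a fixed
  quantile into a nucleus mask (so the realized nucleus fraction is exact);
  a 2-step binary dilation ring around it plays the membrane compartment
  where DAB chromogen accumulates.
- Pseudo-H&E: pink background with purple nuclei plus uniform pixel noise
  of amplitude ≤ 4/255.  Nucleus density (0.22 + 0.08·level) and
  background tint ((−12, −9, +7) per level step) shift monotonically with
  HER2 level, emulating the real correlation of H&E morphology with HER2
  status — without it an H&E-only HER2 classifier would have nothing to
  learn.
- Pseudo-IHC: the *exported deterministic transform* T_level recomputes
  the masks from the stored H&E image alone (nuclei are the only pixels
  with green < 100, robust to the noise amplitude) and recolors: nuclei to
  hematoxylin blue, the ring toward DAB brown with gain (0, 0.25, 0.55,
  0.9) by level, background to near-white.  By construction
  T_level(he) == ihc bit-for-bit, so a conditional generator can drive
  supervised loss toward zero, and the mean warm-channel excess of the IHC
  increases strictly with level.

What passing tests on this task do **not** show: robustness to
registration error, stain variability across labs, tissue morphology
beyond blob masks, or any claim about accuracy on real histology — the
synthetic task validates the machinery (losses, conditioning, training
dynamics, metrics), not clinical performance.

## Complexity accounting and width calibration

Parameters: conv Cin·Cout·k² + Cout, depthwise C·k² + C, linear in·out +
out, affine norm 2C; batch-norm running statistics are buffers, not
parameters.  MACs for one forward pass at side S: conv Cin·Cout·k²·Hout·
Wout (transposed conv under the same output-position closed form),
depthwise C·k²·Hout·Wout, linear in·out; normalizations, activations,
poolings and resampling are not MAC-bearing.  Reported under both
conventions, with 1 MAC = 1 FLOP as the calibrated default and the
forward+backward total taken as 2× forward.

The architecture's channel widths are not fully pinned by its published
description.  The defaults were calibrated once so the *total* system
(both generator paths + three discriminators + classifier) matches the
published complexity figures, then frozen: generator base width 76
(doubling per downsample), inverted-residual expansion 4, level-embedding
32, AdaIN hidden 64; classifier width scale 4.92 with a 69-unit
penultimate layer; discriminator widths fixed at 64→512 as published.
This yields 26,770,629 trainable parameters (26.77 M) and 41.126 GMACs
forward at 256×256 — the printed totals correspond to the full system
composition under the MAC = 1 FLOP convention.  Two independent counters
(closed-form arithmetic and scalar enumeration with shared storage
de-duplicated by identity) must agree exactly; the report constructor
raises otherwise.

## Benchmark scale

CPU-scale runs (tests, acceptance benchmarks) use a reduced-width
configuration: generator base width 8 with expansion 2, classifier width
scale 0.5, discriminators at base width 16 with three body layers (at
64×64 inputs the 1/4-resolution branch is 16 px wide, leaving no room for
a fourth stride-2 layer before the logit convolution).  The synthetic
learnability benchmark trains on 200 pairs at 64×64 for 20 epochs
(seed 0), and the classifier finetunes for 20 epochs with the 12-transform
augmentation; these sizes are the package's benchmark conditions and are
fixed in `benchmark_config()`.

## Numerical choices and degenerate inputs

- Engine: float32 throughout; reverse-mode tape autodiff; im2col + GEMM
  convolutions whose transposed convolution is the exact adjoint of the
  corresponding strided convolution (verified by an inner-product test).
- Instance norm / AdaIN: ε = 10⁻⁵; a constant channel maps to its shift
  parameter (β).
- SSIM: BT.601 luma, 11×11 Gaussian window σ = 1.5 over valid positions,
  K1 = 0.01, K2 = 0.03, C3 = C2/2, exponents α = β = γ = 1 (the universal
  defaults; the general exponent form is implemented), maxval 255 on
  de-normalized 8-bit-range images.  PSNR of identical images returns an
  infinite sentinel with MSE 0.
- FID: Gaussian fits of pooled deep features; the matrix square root via
  `scipy.linalg.sqrtm` with real-part extraction; covariances are checked
  for positive semi-definiteness to −10⁻⁶·scale and the final value is
  clipped at 0.  CS/ED default to flattened raw-8-bit image vectors (the
  feature space for those two columns has no canonical definition;
  config-switchable to deep features).  The deep-feature similarity column
  is the mean cosine similarity of extractor-pooled features of matched
  pairs — an interpretation, labeled as such.
- Pixel-distribution comparison: 256-bin per-channel probability
  histograms; symmetric KL with 10⁻¹² additive smoothing.

## Known limitations

- No pretrained perceptual/Inception weights are bundled or downloaded;
  feature-space metrics use the seeded random extractor by default, so
  their absolute values are not comparable to published numbers computed
  with pretrained backbones (their formulas, invariances and identity rows
  are, and are tested).
- The numpy engine targets desk-scale reproducibility, not throughput;
  full-scale (256×256, 200-epoch) training is documented but impractical
  on one CPU.
- Only power-of-two-friendly input sides (divisible by 16 for the
  generator, 32 for the classifier) are supported; whole-slide handling,
  tiling and registration are out of scope.
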