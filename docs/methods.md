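# Methods

## Model

stainforge translates hematoxylin & eosin (H&E) tiles into S
immunohistochemistry (IHC) stains with a multi-domain, cycle-consistent
GAN.  One H&E-specific encoder/generator/discriminator triple
(E_HE, G_HE, D_HE) is shared by every stain; each stain i adds its own
triple (E_i, G_i, D_i), so a panel of S stains trains S+1 triples
instead of the 2S an independent pairwise CycleGAN per stain would
need.  Training runs two cycles per stain:

```
H&E cycle:    X_HE --E_HE--> Z_HE --G_i--> Y^_i --E_i--> Z^_HE --G_HE--> X^_HE
stain cycle:  X_i  --E_i --> Z_i  --G_HE-> Y^_HE --E_HE-> Z^_i --G_i --> X^_i
```

The architecture follows the ComboGAN split: the encoder carries a stem
convolution, the strided downsampling convolutions and the first half
of the residual blocks; the generator carries the remaining residual
blocks, nearest-neighbour-upsample + convolution stages and a tanh
output stem.  Normalization is per-instance.  The discriminator is a
PatchGAN with two independent branches: one consumes the BT.601
luminance of the input, the other the RGB channels.  Images use a
[-1, 1] internal scale.

Two presets ship with the package.  `paper` mirrors the published
capacity (64 base channels, 4+4 residual blocks, 7x7 stems, 3 strided
discriminator stages).  `tiny` (6 base channels, 1+1 residual blocks,
3x3 stems, 2 strided stages) runs a full forward/backward pass on one
CPU core in well under a second at 64x64 and is the preset every test
uses.

### Numerical backend

The networks run on a small reverse-mode automatic-differentiation
engine written on NumPy (`stainforge._autograd`), providing broadcast
arithmetic, conv2d via im2col, average pooling, nearest upsampling and
the usual pointwise nonlinearities.  Operations preserve the input
float dtype: parameters are float32 for speed, while the loss
functions, when called on float64 inputs (as the oracle tests do),
compute to double precision.  Gradients of every primitive are checked
against central differences in the test suite.

## Annotation-free mask weighting

For each real stain tile X_i an activation mask M_i is extracted by
thresholding in HSV space (hue in degrees with wraparound, saturation
and value in [0, 1]; per-stain ranges live in the stain profile /
config).  With N activated and N-bar background pixels, the dynamic
weights are

    alpha = N-bar / (N + N-bar),    beta = N / (N + N-bar),

so the weight on activated-region terms grows as activation becomes
rare.  Every reconstruction-style loss then adds the pair
`alpha * L(M . a, M . b) + beta * L(M-bar . a, M-bar . b)`.

Numerical conventions chosen here (the equations leave them open):

* **Masked means are global.**  Masked terms multiply by the mask and
  average over *all* pixels.  alpha/beta already rebalance the two
  regions, and this convention keeps every masked term bounded by its
  unmasked counterpart; it is also the only reading under which the
  adversarial corner identities (e.g. an all-ones mask forcing the
  complement term to exactly 1) hold.
* **Base distances.**  L1 for image and latent reconstruction terms,
  least squares against constant target maps of 1/0 for adversarial and
  discriminator terms — the CycleGAN-family conventions.  Both are
  switchable (`kind`, config).
* **Dual heads in scalar losses.**  The loss equations write a single
  D(.); the two head grids share their spatial extent, so the package
  stacks them into one tensor and applies the printed formula to the
  stack, which equals averaging the per-head losses.
* **Mask alignment.**  Where a mask meets a discriminator patch grid or
  a latent grid, it is area-resampled (bilinear on the float mask) and
  re-binarized at 0.5.
* **Degradation operator.**  3x3 average pooling at stride 2 without
  padding (out = floor((in-3)/2)+1); masks are pooled the same way and
  re-binarized at 0.5.

## Objective and schedule

Per stain: `L_IHC,i = lambda_cyc * L_cyc,i + lambda_adv * L_adv,i +
lambda_reg * L_reg,i`, with the supervised loss added at weight
`lambda_sup` in the paired setting.  Defaults: lambda_cyc = 10,
lambda_adv = 1 (the published configuration), lambda_D = 0.5 (the
halved discriminator loss customary in this family), lambda_sup = 1.
The regularizer `L_reg = lambda_idt * L_idt + lambda_lat * L_lat +
lambda_fwd * L_fwd` defaults to identity + forward enabled and latent
disabled — the combination the ablation study found strongest (the
latent term consistently hurt) — and is active by default only in the
unpaired setting, where direct correspondences are unavailable.

Each training iteration sweeps the stains in a fresh uniform random
permutation; per stain, the generator-side step updates E_i, G_i and
the shared E_HE, G_HE, then D_i and D_HE are updated against the
detached fakes.  After the sweep, the mean of the per-stain synthesis
losses refines E_HE and G_HE *only*.  The gradient of that mean equals
the mean of the per-stain gradients on the shared components, so the
implementation retains those gradients during the sweep rather than
re-running the forward passes; the balancing update is still a distinct
optimizer step and leaves every per-stain parameter bit-identical.

Optimization is Adam (beta1 = 0.5, beta2 = 0.999) at lr0 = 2e-4, held
for `n_fixed_epochs` and then decayed linearly:
`lr(e) = lr0 * (1 - (e - n_fixed)/n_decay)`, so the final decay epoch
runs at lr0/n_decay and the (virtual) next epoch would be exactly 0.
Augmentation is limited to flips and quarter-turn rotations; paired
tiles receive the identical draw.  Batch size defaults to 1 — the
published configuration uses 6 on data-center hardware; desk-scale CPU
runs use single-tile batches.  An epoch is one pass over the smallest
stain's tile list unless `iterations_per_epoch` overrides it.

## WSI stitching

Tiles are generated on an overlapping grid (default overlap 0.6; 0 and
0.3 retained for comparisons), multiplied by the separable 2-D Hamming
window `w(x, y) = h(x) h(y)`, `h(t) = 0.54 - 0.46 cos(2 pi t/(M-1))`,
and accumulated together with the window weights; the final raster is
the weighted sum divided by the accumulated weight.  Where exactly one
tile covers a pixel the window cancels, so single-coverage regions are
exact; no separate window renormalization is needed.  Accumulation is
float64 and quantization (round half away from zero) happens once at
the end.  Boundary tiles are clamped inward, never padded, so edges can
exceed the nominal overlap — harmless under weight normalization.
Output rasters are written as tiled pyramidal TIFFs whose levels halve
(rounding up) until <= 256 px.

## Self-inspection

The trained discriminator doubles as an anomaly detector.  Head maps
are clamped to [-1, 1], bilinearly resized to the input size, fused by
a pixel-wise minimum and normalized: `C_all = (min(C_lum, C_rgb)+1)/2`
(0 anomaly, 1 authentic).  The *population* standard deviation of
C_all, in percent, summarizes a tile; an acceptance band for it is
calibrated as empirical quantiles (default 0.025/0.975, >= 100
authentic tiles) and applied as a closed interval — below the band is
flagged as background-like, above as artifact-like.  Heatmaps map C_all
through the classic piecewise-linear Jet ramp with the index inverted
(1 - C_all) by default so anomalies render red.

## Synthetic fixtures

The fixture generator provides the controlled ground truth real tissue
cannot: H&E-like tiles (smoothed-noise eosin background, elliptical
hematoxylin nuclei), per-stain counterparts built as invertible affine
color transforms of the H&E tile (diagonally dominant matrix with
contrast 0.30 plus a gray tint offset, keeping tissue saturation below
every extraction band), and activation blobs painted hard in a color
strictly inside the stain's HSV range.  The blob process targets an
activation fraction p within +-10% and the painted count is exactly
recoverable by thresholding (IoU 1.0 in practice; >= 0.99 asserted).
Eight default profiles (AE1AE3, CD117, CD15, CD163, CD3, CD8, D240,
GIEMSA) spread activation hues 40 degrees apart; GIEMSA exercises a
wrapping red range.  Three degradation modes emulate slide-quality
failures: a global channel gain/offset shift, disjoint opaque dark
contamination blobs, and a water-droplet-like local blur with a bright
ring; each returns the exact corruption mask.

Because each synthetic stain is a pixel-wise invertible function of
H&E plus sparse activation, a tiny model can genuinely learn the
mapping — the training smoke test is meaningful, not vacuous.  The
fixtures deliberately do *not* emulate scanner formats, slide-level
tissue layout, inter-patient variability, stain batch effects or
out-of-focus optics, so passing tests demonstrate the mechanics of the
method, not clinical-grade synthesis quality.

## Desk-scale protocol sizes

Tests and the acceptance script use: S = 2 stains, 64x64 tiles, 16
training tiles per domain, batch size 1, 200 training iterations,
three seeds per setting, six held-out pairs per stain for evaluation,
and degradation severity 0.5.  At these sizes one training run takes
roughly one to two CPU-minutes.

## Known limitations

* **Clamp saturation on out-of-distribution content.**  The confidence
  map clamps raw patch responses to [-1, 1].  A briefly-trained tiny
  discriminator can produce strongly positive (not negative) raw
  responses on content unlike anything seen in training — dark opaque
  contamination blobs in particular act as a super-stimulus for the
  luminance head — and the clamp then *raises* mean C_all above the
  authentic level instead of lowering it.  Global color shifts and
  droplet blur are separated correctly at desk scale; dark-blob
  contamination is not.  At full scale (hundreds of epochs, tens of
  thousands of tiles) the discriminator's learned manifold is far
  tighter, and this failure is not expected to persist; the std-based
  QC gate also flags such tiles regardless of the mean.
* The per-stain HSV ranges are configuration, not learned; real DAB /
  chromogen thresholds must be tuned per laboratory.
* The engine is CPU-only and single-threaded; the `paper` preset is
  provided for architectural fidelity, not for full-scale training,
  which remains out of desk-scale reach.
* Tissue detection is a luminance-threshold proxy
  (`core_io.foreground_fraction`), not a validated tissue segmenter.
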