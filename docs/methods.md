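# Methods

This note documents the models, defaults and numerical choices behind
`ldsefocus`: what the simulator assumes, how the network is built and
trained, and what the synthetic benchmark does and does not demonstrate.

## Problem setting

Single-shot focus prediction treats autofocus as regression: given one
defocused micrograph (or a 224 px tile of one), estimate the signed axial
distance z (in micrometres) between the current stage position and the
focal plane, so the stage can be corrected in a single move instead of
sweeping a sharpness-maximising search. The regression target is the
stage offset recorded when the training stacks were acquired.

## Thin-lens defocus geometry

The optics module works entirely in the geometric (ray) picture. A lens
of focal length f images an object at distance u onto the conjugate plane
at v with 1/u + 1/v = 1/f. With the sensor fixed at distance s, the blur
circle radius on the sensor is

    R = (s·D/2) · |1/f − 1/u − 1/s|,

zero exactly when s equals the conjugate distance. A stage offset z moves
the object to u − z (positive z = sample raised toward the objective),
and R(z) follows by re-evaluating the formula at the displaced object
distance. The relation between R and z is kept in this composed form
rather than a linearised small-defocus approximation; near z = 0 it is
R ≈ c·|z| and the implementation is verified against finite differences.
R is reported as a magnitude — the *sign* of the defocus is carried by z.

Wave optics, diffraction and chromatic effects are out of scope; the PSF
is a rasterised geometric blur disk (anti-aliased by 4×4 subpixel area
sampling; a Gaussian with σ = R/2 is available as an option), and radii
below half a pixel collapse to the identity kernel to avoid aliased
one-pixel stencils. All lengths are micrometres; pixels enter only when a
kernel is rasterised, via the sensor sampling pitch `pixel_size`
(default 4.4 μm/px, an effective 2×-binned camera pitch that keeps the
largest kernels at ~15 px for 64 px tiles).

The bundled lens stand-ins are thin-lens equivalents of dry objectives:
20X/0.25 NA (f = 9 mm, in-focus u = 9450 μm) and 40X/0.65 NA
(f = 4.5 mm, u = 4612.5 μm), with the aperture diameter derived from the
NA half-angle. The 40X lens blurs several times faster per μm of defocus,
which reproduces the qualitative observation that higher-magnification
fields are harder to predict.

## Why the simulated PSF is asymmetric in the sign of z

For any realistic microscope geometry the *geometric* blur radius is
symmetric in z to a fraction of a percent, so a simulator that only blurs
with a symmetric kernel produces (near-)identical images at +z and −z.
Signed regression would then be information-theoretically impossible: the
MSE-optimal predictor collapses to ≈0 and no architecture could recover
the sign. Real micrographs do not have this degeneracy — three well-known
through-focus asymmetries break it, and the renderer models all three:

1. **Phase-contrast reversal (transport of intensity).** Semi-transparent
   specimens gain defocus contrast proportional to z and to the Laplacian
   of their optical thickness: rims go bright on one side of focus and
   dark on the other. The renderer proxies optical thickness by the
   specimen's absorption relief, band-limits its Laplacian (Gaussian
   Laplacian, σ = 1.5 px, normalised to unit standard deviation) and adds
   `tie_strength`·z of it to the sharp image before blurring. Default
   `tie_strength` = 0.03 per μm: at z = 10 μm the rim modulation is ±0.3
   of full scale, comparable to strongly defocused bright-field frames.
   This term is the dominant sign cue and also restores sensitivity to
   sub-pixel defocus near z = 0, where the blur kernel is the identity.
2. **Spherical aberration.** The blur disk's radial profile is tilted by
   `psf_asymmetry`·sign(z) (default 0.6): rim-weighted (ring-like) above
   focus, centre-weighted below.
3. **Residual astigmatism.** The disk is stretched by 1 + e along x and
   compressed by the same factor along y above focus, and conversely
   below (`psf_astigmatism`, default e = 0.25), preserving area — the cue
   exploited deliberately by cylindrical-lens axial localisation.

These three coefficients are acquisition conditions of the synthetic
study, fixed once; they are not fitted to any network.

## Cell phantoms and the acquisition protocol

A phantom field is a bright background (0.85) carrying n darker
soft-edged ellipses (sigmoid rim of width 0.08 in normalised elliptical
radius; absorption depth 0.3–0.5 with internal Gaussian-filtered texture)
plus low-amplitude background texture (σ = 3 px, amplitude 0.08). The
rightmost `blank_fraction` (default 25%) of columns is background-only —
the stand-in for empty glass, used to exercise blank-tile rejection.
Everything is deterministic in the recipe's seed.

A stack sweeps z from −10 to +10 μm in 0.5 μm steps (41 frames — note
that acquisition protocols with this grid are often loosely described as
"about 40 images", but the closed grid includes both endpoints and the
in-focus frame; with zero sensor noise the z = 0 frame is the
sharpest by variance-of-Laplacian, and equals the phantom exactly).
Gaussian sensor noise (σ = 0.01) is added per frame. Frames are cut into
non-overlapping tiles (edge remainders discarded), each labelled with its
frame's z; datasets are split into train/test *by field*, because
tile-level splits would leak near-duplicate content between the sets.
Note the phase-contrast term means a slightly defocused frame can have
*higher* mean gradient energy than the focal frame — as for real
semi-transparent specimens — while the variance-of-Laplacian measure
still peaks at focus.

Tiles whose foreground fraction or intensity spread falls below the blank
discriminant's thresholds (below) are excluded from training and
evaluation: they carry no defocus information, and a quarter-blank field
would otherwise put a ~3 μm floor under any achievable test RMSE.

## LDSE-NET

The network is a lightweight DenseNet-style regressor with a Tanh-gated
squeeze-and-excitation module:

* stem: 7×7 conv (stride 2, pad 3) → BN → ReLU → 3×3 max pool (stride 2);
* body: dense blocks whose layer L receives the concatenation
  [X₀, …, X_{L−1}] and emits k = `growth_rate_k` channels through a
  pre-activation BN→ReLU→3×3-conv composite, so a block entered with C₀
  channels exits with C₀ + L·k; each block is followed by a transition
  (BN → **Tanh** → 1×1 conv compressing channels by `transition_reduction`
  → 2×2 average pool);
* attention: one squeeze-excitation module on the final feature map —
  squeeze is the per-channel spatial mean, excitation is a bottleneck MLP
  (C → ⌈C/r⌉ → C, ReLU inside) with a **Tanh** output gate, and the gates
  rescale channels multiplicatively;
* head: global average pooling → fully connected → one scalar.

Activation placement follows the "replace some activations with Tanh"
idea deterministically: ReLU stays inside dense-layer composites, Tanh is
used in transitions and as the excitation gate. The Tanh gate lives in
(−1, 1) and is deliberately *not* clamped to (0, 1): a negative gate may
flip a channel's sign, and a config switch (`se_gate="sigmoid"`) restores
the conventional gate for ablation.

The default configuration — 3 blocks of 4 layers, growth rate 12, stem 24
channels, reduction 0.5, r = 4 — brings a 224×224 input to a 7×7 map
before the head and stores 84,061 float32 parameters ≈ 328 KB, inside the
sub-480 KB lightweight budget the architecture targets. The exact layer
counts of a published checkpoint are not knowable from a size budget
alone, so every structural hyperparameter is exposed in `LDSENetConfig`.

Labels are normalised to [−1, 1] over the configured axial half-range
(default 10 μm) for training — the Tanh-rich network trains much more
stably on unit-scale targets — and predictions are mapped back to μm.
The normalisation is exact bookkeeping: MSE on normalised labels is raw
MSE divided by the squared scale.

All layers are implemented directly on NumPy with explicit
forward/backward passes (convolution via im2col + BLAS matmul); the
whole stack runs in float32 for training and float64 for gradient
checking, where backprop agrees with central finite differences to
better than 1e-4 relative on a two-block configuration.

## Training regimen

Adam (β = 0.9/0.999) at learning rate 1e-3, batches of 50 tiles, learning
rate multiplied by 0.5 every `lr_decay_every` epochs (default 20; the
scaled benchmark uses 12 to settle its shorter runs). "Stop when the
losses stabilise" is operationalised as: stop once the best test loss has
failed to improve by more than 1% relative for `plateau_patience`
(default 10) consecutive epochs; the returned weights are those of the
best test-loss epoch, never the last one. Horizontal/vertical flip
augmentation is on by default — flips preserve both the defocus level
and the astigmatism axes (a 90° rotation would not). Divergence
(non-finite loss) aborts with a diagnostic rather than continuing.
Data order, initial weights and augmentation are all driven by explicit
seeds, so a rerun reproduces the loss trace bit for bit.

## Wide-field inference

A wide-field image is cut into the non-overlapping tile grid (right/
bottom remainders truncated; row-major 0-based indices). Each tile passes
the blank discriminant: foreground pixels are those deviating from the
tile's modal intensity (64-bin histogram mode) by more than 3× a robust
noise scale (1.4826·MAD of near-mode pixels, floored at 1e-3); a tile is
kept iff its foreground fraction ≥ `f_min` (0.1) *and* its intensity
standard deviation ≥ `s_min` (0.01), both inclusive. The field estimate
D_p is the unweighted mean of kept-tile predictions — confidence
weighting was deliberately not added — and is absent (with explicit
status) when every tile is discarded. D_p is invariant to tile
enumeration order, never influenced by discarded tiles, and bounded by
the extreme kept-tile predictions.

The 3×3 regional analysis partitions the image into nine non-overlapping
regions (remainder truncated) and runs the same prediction independently
in each, reporting |prediction − z_true| per region.

## The scaled benchmark (`ldsefocus.bench`)

Full-scale training (224 px tiles, ~10⁵ patches) is a GPU-scale job, so
the package's self-check runs the identical pipeline at reduced size,
chosen to finish in minutes on one CPU core: five 256 px fields, 64 px
tiles, the full ±10 μm / 0.5 μm grid, a 9:1 field split, blank filtering
(~1950 content tiles), and a reduced network (stem 16, two blocks of
three layers, k = 10, 20,158 parameters ≈ 79 KB). Training runs at most
70 epochs with patience 18 and the learning rate halved every 15. Wide-field recovery is probed on a fresh,
fully-populated 192 px field rendered at a true offset of +3 μm, through
both `predict_focus` and the 3×3 regional analysis.

## What passing the benchmark does and does not show

The phantom study validates the machinery — architecture arithmetic,
gradients, the training loop, blank rejection, aggregation — and shows
that the network recovers the generative parameter (signed defocus) from
images whose through-focus behaviour follows the modelled physics. It
does not demonstrate performance on real stained tissue: phantoms have
no stain variability, no depth structure within the specimen, no camera
nonlinearity or illumination drift, and their through-focus asymmetries
are cleaner than any real optical train's. Accuracy figures from the
benchmark are therefore comparable in *kind*, not in magnitude, to
numbers measured on real microscope data.

## Numerical and degenerate-input choices

* Sub-pixel blur radii (< 0.5 px) return the identity kernel.
* Kernels larger than `max_radius_px` (64) raise an excessive-defocus
  error instead of silently producing enormous convolutions.
* Max-pool ties resolve to the first window element; transitions floor
  odd spatial sizes; channel compression floors to at least one channel.
* The SE bottleneck width is ⌈C/r⌉ so any (C, r) pair is valid.
* Batch-norm uses ε = 1e-5 and momentum 0.1 running moments; evaluation
  always uses running statistics.
* `split_dataset` clamps the field split so both sides are non-empty and
  refuses fewer than two fields.
* Histogram bins in reports are 50 nm wide across ±1 μm with two
  overflow bins, so the ±250 nm headline band is resolved exactly.
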