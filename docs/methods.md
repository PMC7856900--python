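# Methods

## The problem

Optical-resolution photoacoustic microscopy (OR-PAM) images hemoglobin
contrast at micrometer resolution, but laser dosage, imaging speed and
image quality constrain each other: scanning faster within the tissue
safety (fluence) limit forces a lower per-pulse energy — the
photoacoustic amplitude drops while detector noise does not — and
sparse (undersampled) scanning trades pulse count against spatial
resolution. This package implements a learned reconstruction that
recovers full-sampling, full-energy-quality, vessel-enhanced images
from dual-wavelength acquisitions taken at a fraction `f` of the limit
pulse energy with `s`-fold per-axis undersampling, a total dosage
reduction of `s²/f` (32-fold at f=1/2, s=4; 16-fold at f=1/4, s=2).

## Model

The restorer is a multitask residual dense network (MT-RDN) with three
subnetworks. Subnetworks 1 and 2 each process one wavelength channel
(532 nm and 560 nm inputs at low resolution) and output full-resolution
restored channels; subnetwork 3 takes the channel concatenation of
those two outputs (scale 1, two input channels) and produces the fused,
vessel-enhanced product. Each subnetwork is a residual dense network:
two shallow-feature convolutions, D residual dense blocks (C densely
connected 3×3 conv + ReLU stages of growth G, a 1×1 local-fusion
convolution, local residual), 1×1 + 3×3 global feature fusion over the
concatenated block outputs, a global residual to the first shallow
feature map, sub-pixel (pixel-shuffle) upsampling by the undersampling
factor, and a final reconstruction convolution. The network is fully
convolutional; any input of at least 8×8 pixels is accepted.

Supervision is multitask: the loss is `w1·L(o1,g1) + w2·L(o2,g2) +
w3·L(o3,g3)` with L = mean absolute error and weights normalized to
sum to one. The three targets are the full-sampling full-energy 532 nm
image, the same at 560 nm, and the 532 nm image enhanced by the
multiscale vesselness filter (below). Defaults `(0.25, 0.25, 0.5)` give
the fused branch the largest share, since the fused output is the
product of interest; the weights are exposed as configuration.

Defaults D=4, C=4, G=16, G0=32 are a small profile suitable for
CPU-scale experiments (≈5·10⁵ parameters over the three subnetworks);
the full-scale published RDN profile (D=16, C=8, G=64) is reachable
through the same configuration. MAE was chosen over MSE as the
restoration loss for its robustness to the heavy-tailed residuals that
clipped noise produces. The fusion subnetwork sees only the two branch
outputs, not the raw inputs.

### Numerics and initialization

The network runs on a small NumPy reverse-mode autodiff engine
(float32, NHWC, im2col convolutions; the input gradient of a stride-1
same-padded convolution is computed as a convolution with the flipped,
channel-transposed kernel, so the backward pass is matmul-only).
Initialization is He-normal, with the local/global fusion, upsampling
and reconstruction convolutions scaled by 0.2: with plain He init the
dense-block accumulations make the initial outputs two orders of
magnitude too large (initial loss ~33 instead of ~0.11) and early
optimization is wasted recovering from it. Optimization is Adam
(lr 10⁻³, β=(0.9, 0.999)), mini-batches shuffled per epoch from a
dedicated seeded RNG; training is a pure function of (data, model seed,
optimizer seed) on a fixed platform. A non-finite loss raises
immediately with the offending step.

## Synthetic phantoms

The in-vivo datasets the method was designed for are not distributable,
so every stage is exercised on synthetic scenes that reproduce the
relevant statistical structure of OR-PAM maximum-amplitude projections:
bright curvilinear vessels of several calibers on a dark background,
two spectrally coupled channels, and per-vessel oxygenation.

A scene is built from a random piecewise-linear branching tree (roots
start on the field border; each segment spawns 0–2 children with radius
= parent × U(0.6, 0.9), turn angle 15–50°, depth-limited), rasterized
with an anti-aliased capsule/disk brush. Root oxygen saturation is
drawn from an arterial (0.85–0.98) or venous (0.55–0.75) mode and
jittered N(0, 0.02) along branches. Per pixel, the absorption at
wavelength λ is `coverage · (ε_HbO2(λ)·sO2 + ε_Hb(λ)·(1−sO2))`; the
default extinction table treats 532 nm as exactly isosbestic and gives
deoxy-hemoglobin the stronger 560 nm absorption. Channels are blurred
by an isotropic Gaussian point-spread function (default FWHM 2.5 px)
and offset by a small background level (default 0.02).

Both channels are normalized **jointly** (one min/max over the pair).
Per-channel min-max would rescale the two wavelengths differently and
destroy the per-pixel spectral ratio; with joint normalization and a
background that is the scene minimum, normalization is a single global
affine map, so the ratio — and therefore sO2 — survives exactly. A
constant scene normalizes to all-zero by convention.

What the phantoms do *not* model: acoustic propagation, depth-dependent
fluence, vessel tortuosity beyond piecewise-linear segments, motion,
and tissue background texture. Passing tests therefore demonstrate the
pipeline's correctness and the restoration's behaviour *in kind*
(metrics improve under the trained network), not in-vivo magnitudes.

## Degradation forward model

Per-pulse energy fraction `f` scales amplitudes linearly; detector
noise is additive zero-mean Gaussian (default SD 0.05 on the normalized
scale — the noise SD of real systems is instrument-specific and is a
free simulation parameter), applied after scaling, so image SNR scales
∝ f; the result is clipped back to [0, 1]. Undersampling keeps every
s-th row and column (pure decimation, no interpolation), matching the
patch-size arithmetic of the training geometry (e.g. 200×200 tiles give
100×100 inputs at s=2 and 50×50 at s=4). The two wavelength channels
receive decorrelated noise streams spawned from one seed. Energy
scaling and decimation commute when noise is off.

## Vesselness enhancement target

The enhancement target is the standard 2-D multiscale Hessian
vesselness (Frangi) filter of the 532 nm ground truth: at each scale σ
the scale-normalized (×σ²) Gaussian-derivative Hessian is
eigendecomposed (|λ1| ≤ |λ2|); for bright-on-dark vessels the response
is zero where λ2 > 0 and otherwise
`exp(−R_B²/2β²)·(1−exp(−S²/2c²))` with blobness R_B = λ1/λ2 and
structureness S = √(λ1²+λ2²); the final map is the pixelwise maximum
over scales, min-max normalized. Defaults: σ ∈ {1, 2, 3, 4} px,
β = 0.5, c = "auto" = half the per-scale maximum structureness (with a
1e-12 floor so numerically flat scales contribute nothing).

Derivative kernels are sampled Gaussians with moment corrections
(zero DC and exact second moment for the second-derivative kernel;
unit first moment for the first-derivative kernel): naively sampled
kernels keep a ~10⁻⁷ DC residual that turns flat or polynomial regions
into spurious vesselness.

## Metrics

PSNR is `20·log10(max(ref)/RMSE)` with the peak taken from the
reference; identical images raise an explicit infinite-PSNR error.
SSIM is the three-term luminance·contrast·structure product computed
from **global** image statistics (population variance convention), as
a single product per image — not the sliding-window variant (offered
behind a flag but not canonical here, where test patches are small and
homogeneous). The contrast term uses twice the covariance in its
numerator, `(2σ_ref,rec + c2)/(σ_ref² + σ_rec² + c2)`, so the product
collapses to the common two-term SSIM only when the covariance equals
the SD product. Constants default to c1 = (0.01L)², c2 = (0.03L)²,
c3 = c2/2 with L = 1; with c3 = 0 and zero variances the structure term
is defined as 1. Line-profile SNR is the peak of a linearly
interpolated profile divided by the sample SD of a disjoint background
box — the peak/SD convention is a documented choice, since profile SNR
figures rarely state theirs. Distribution summaries use the sample
(n−1) SD. Error maps are pixelwise |ref − rec|.

## sO2 unmixing

Per pixel, the two wavelength amplitudes are solved against the 2×2
extinction matrix for relative HbO2/Hb concentrations;
sO2 = C_HbO2/(C_HbO2+C_Hb), clipped to [0, 1], NaN where total
hemoglobin is non-positive. sO2 is a ratio and hence invariant to the
one global scale that joint normalization applies — the reason the
noiseless phantom round trip recovers the true sO2 to 10⁻⁶ on vessel
pixels. Masking by a thresholded image (original, vesselness-filtered,
or the fused reconstruction) only selects pixels; retained values pass
through bit-identically.

## Patching, stitching, training geometry

Images are tiled row-major into square low-resolution patches; when the
patch does not divide the image, the last tile in each axis is shifted
inward so coverage is complete. Stitching places each patch at
`origin × scale` and averages overlaps; default stride equals the patch
size (no overlap), with overlap-averaging available because seams
otherwise appear at tile borders. Patches across the five image roles
(two inputs, three targets) are paired by identical origins.

## Standard desk-scale experiment

`pamrestore.experiments.restoration_experiment` is the package's
canonical configuration: 20 scenes of 128×128 px, f = 1/2, s = 2,
noise SD 0.05, 16/4 train/test split, LR patch 16, batch 4, 500 Adam
steps, small-profile network. These sizes keep a full run in the
minutes range on one CPU while every stage is exercised; quality is
reported as held-out PSNR/SSIM of the fused output against the
vesselness target, with nearest-neighbor upsampling of the raw 532 nm
input as the no-learning baseline, plus the first/last 100-step moving
averages of the training loss.

## Known limitations

- Global-statistics SSIM values are not comparable to windowed SSIM
  numbers from other software.
- The phantom's extinction coefficients are stylized (exact isosbestic
  532 nm); absolute sO2 accuracy on real spectra is out of scope.
- Bit-exact reproducibility holds per platform/BLAS, not across them.
- Training at the published full data scale (thousands of tiles,
  full-scale RDN profile) is configuration-reachable but not exercised
  by the test suite.
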