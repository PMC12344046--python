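# Methods

## Problem and approach

Cone-beam CT acquired on the treatment machine guides radiotherapy but
suffers scatter-induced shading, streaks, noise, and low soft-tissue
contrast relative to the fan-beam planning CT.  This package implements a
per-slice *internal learning* approach to quality transfer: for each CBCT
slice and its deformably registered planning-CT counterpart, a small
residual convolutional network is trained from scratch on augmented crops of
that single pair, then applied to the full slice.  No external training
corpus exists anywhere in the pipeline; each slice pair is its own training
set, so domain shift between a training population and the patient at hand
cannot arise.

## Representation and gradation

All images are carried on a 16-bit integer "display" scale `[0, 255²] =
[0, 65025]`.  Stored scanner values `D` become CT numbers `C = slope·D +
intercept` (air −1000 HU, water 0); windowing maps
`[center − width/2, center + width/2]` affinely onto the display range and
clips:

    P = round(65025 · (C − m) / width),   m = center − width/2.

The rounding rule is half-away-from-zero, applied after scaling.  The rule
itself is a package decision (the display formula is real-valued); it is
deterministic and makes every stage bit-reproducible.  The CBCT slice's
window is read once per patient and applied to both modalities; raster
inputs without metadata fall back to center −120 / width 1440 HU, covering
the [−840, 600] HU pelvic soft-tissue range.  Networks consume images
divided by 65025; `denormalize` (scale, round, clip) inverts exactly on
integer display images.

## Pairing and registration

CBCT and planning-CT series differ in slice thickness and count, so each
CBCT slice takes the planning-CT slice nearest in scan-axis position (ties
toward the smaller position) — a deterministic, automated surrogate for
manual slice matching.  The planning-CT slice is bilinearly resampled onto
the CBCT pixel grid, center-aligned, then registered by a 2-D B-spline
free-form deformation (SimpleITK): Mattes mutual information with 32 bins,
three-level coarse-to-fine pyramid, gradient-descent line search with 200
iterations per level, dense metric sampling.  The control-point spacing
default is 16 px: recovery experiments on synthetic sinusoidal fields with a
64-px wavelength showed that a 32-px grid cannot represent the deformation
(mean endpoint error ≈ 2.4 px) while 16 px recovers it to ≈ 0.8 px.  Dense
sampling keeps the optimization free of sampling noise and hence
deterministic.

Deformation fields are `(H, W, 2)` arrays of (row, col) pixel displacements
on the fixed grid, applied by backward bilinear warping with edge
replication.  Note an asymmetry that matters for evaluation: registering an
image that was *backward-warped* by a field `u` recovers (approximately) the
*inverse* of `u`, not `−u`; the package provides a fixed-point field
inverter so recovery error is measured against the correct ground truth.

## The network

Eight pre-activation blocks (rectifier, then 3×3 convolution, stride 1,
padding 1): 1→128 channels, six 128→128 blocks, 128→1, with a global skip
connection adding the input to the branch output.  The first rectifier is a
no-op on [0, 1] inputs; the output block applies no extra non-linearity
before the residual add.  Two consequences are load-bearing and tested:
with all-zero weights the network is *exactly* the identity (the residual
branch vanishes), and because every layer preserves spatial size the same
parameters apply to any image size — training on crops, inference on full
slices.

The network is implemented directly in numpy: each convolution is an im2col
patch-matrix product (one BLAS call per layer), gradients are the standard
transposed-convolution/patch-product pair, verified against central finite
differences through the full eight-layer composition.  Parameters are
float32; the residual add happens in float64 on the original input.
Initialisation is Kaiming fan-in scaling with the run seed, zero biases.

## Training

Each step draws one augmented sample: rotation uniform over
{0°, 90°, 180°, 270°}, left–right flip with probability ½, crop origin
uniform over all placements that keep the crop inside — the identical
transform applied to input and target.  The loss is mean squared error on
the normalized patches, minimised with Adam (β₁ = 0.9, β₂ = 0.999,
ε = 1e−8), batch size 1, sampling on the fly rather than pre-building an
expanded dataset (statistically equivalent, memory-free).  No downscaling is
applied anywhere: the degraded/clean roles are played by the two modalities.

The learning rate starts at 1e−3.  Every `check_period` steps the mean loss
of the period is recorded; once `fit_window` records exist, a least-squares
line is fitted to them.  With `s = |slope|·fit_window` (predicted decrease
over the window) and `σ` the residual standard deviation, `σ > s` divides
the rate by 10, after which the recorded window restarts — one detected
plateau causes one division, not a cascade.  When a division would undercut
1e−6, training terminates instead; `max_steps` is a hard cap.  The period,
window and comparison factor are not pinned down by the method's published
description; the defaults (60-step period, 5-record window, factor 1) follow
internal-learning practice and are all configurable.  With a 5-point fit the
rule is intentionally permissive — on a true plateau a single check triggers
with roughly even odds, so divisions happen within a few checks — which
matches its role as a coarse annealing heuristic, not a convergence test.

Two presets exist: the full-scale configuration (128 channels, 128-px
crops, up to 3000 steps) and a desk-scale preset (32 channels, 48-px crops,
20-step checks, up to 600 steps) sized so that a slice pair trains in about
half a minute on one CPU core.  All shipped studies and tests use the
desk-scale preset; at this size training typically passes three LR
divisions and is near its 1e−6 floor when the step cap lands.

## Inference: geometric self-ensemble

The trained network is applied to the eight square symmetries of the slice
(4 rotations × optional left–right flip); each output is transformed back,
and the per-pixel median of the eight aligned outputs (mean of the 4th and
5th order statistics) is denormalized, rounded and clipped.  Because the
transform set is the full dihedral group, the fused output is equivariant
under any of its elements, up to float round-off from re-ordered
convolution sums (observed ≤ 1 display unit); the property is asserted in
the tests.  Square inputs are required, since quarter-turn rotations must
stay on one grid.

## Metrics

NMI, RMSE, PSNR and SSIM are computed on display images rescaled to
[0, 255] (real-valued, dynamic range L = 255).  This dialect is fixed by an
internal-consistency argument: the reported patient means satisfy
`20·log10(255/11.70) = 26.77 ≈ 26.85` dB, so RMSE and PSNR were evaluated
on a 255-range scale.  SSIM uses a 7×7 uniform window with unbiased
covariance (an 11×11 Gaussian dialect is selectable); RMSE is the plain
root-mean-square difference; PSNR is `20·log10(L/RMSE)` with an infinity
sentinel for identical images.  NMI defaults to symmetric uncertainty
`2·I/(H_A + H_B) ∈ [0, 1]` — the published values (≈ 0.44–0.58) lie below
1, which rules out the common `(H_A + H_B)/H_{AB} ∈ [1, 2]` normalisation,
also available as the `studholme` variant.  Joint histograms use 256 bins
over the fixed display range, not per-image extrema, so values are
comparable across methods.  Reports aggregate per patient (mean, SD) and
then per method over patients.

## Total-variation baseline

The comparator minimises `½‖u − f‖² + λ·TV(u)` (isotropic TV, forward
differences, reflective boundaries) by Chambolle's dual projection, with
per-iteration objective logging so monotone descent is testable.  Default
λ = 8 metric-scale units (~0.03·L), 200 iterations, 1e−4 relative-change
tolerance.  The weight is deliberately not calibrated: the baseline's role
is comparative.  On the shipped phantoms this weight over-smooths (RMSE
slightly worsens while noise is removed), which is reported as measured.

## Synthetic phantom suite

The patient data behind the method is private, so all end-to-end evidence
comes from a generator of paired pelvic-like phantoms with known ground
truth.  The clean slice is piecewise smooth in CT numbers: air background
(−1000 HU), water-density body ellipse, an iliac-like bone ring (700 HU),
bladder (30 HU), gas-filled rectum (−950 HU), paired muscle regions
(55 HU), mild smooth soft-tissue texture (25 HU SD), with per-seed jitter of
structure geometry.  The CBCT-like counterpart adds, in order: a radial
cupping field (default amplitude 60 HU), a sparse comb of straight streaks
through the body center with a Hann radial taper (12 streaks, 40 HU),
Gaussian noise (20 HU), and 0.8-px Gaussian blur, clamped to [−1100, 1700]
HU before windowing.  Amplitudes were chosen once to land the degraded
pair in the visually and quantitatively plausible range for pelvic CBCT
(RMSE ≈ 11–12, SSIM ≈ 0.94, NMI ≈ 0.46 against the clean target on the
metric scale).  An optional smooth sinusoidal deformation of the clean
image exercises registration against a known field.

What the phantoms do *not* emulate: physically accurate cone-beam scatter
(the streaks are geometric, not projected), 3-D volumes, real anatomical
variability, metal or motion artifacts, or the modality-specific intensity
relationship between real CBCT and fan-beam CT.  Passing the phantom suite
shows the pipeline's mechanics — training converges, enhancement moves a
degraded slice toward its paired target, registration recovers smooth
misalignment — not clinical performance on patient data.

## Study sizes and numerical choices

The shipped improvement study uses 10 phantom pairs at 128×128 with the
desk-scale preset (a few minutes on one CPU); the registration study uses
one 128×128 phantom with a 3-px, 64-px-wavelength field.  Per-pair seeds
derive as `master_seed + pair_index`; every random draw (phantom geometry,
degradation, weight init, augmentation) flows from these.  Degenerate
inputs are handled explicitly: crops larger than the image shrink to the
full side with a warning; constant images in NMI return the ideal/minimal
value with a degenerate-input flag; identical images in PSNR return an
infinity sentinel; registration failure returns the best-so-far transform
flagged in provenance.

## Known limitations

- 2-D per-slice processing only; no volumetric registration or enhancement.
- One network per slice pair means runtime scales linearly with slice count
  (by design — it is the price of needing no training corpus).
- The numpy engine is single-threaded BLAS-bound; it is sized for desk-scale
  experiments, and the full 128-channel configuration is correspondingly
  slow on large slices.
- Registration quality bounds enhancement quality: residual misalignment
  between the pair is learned as if it were appearance difference.
- Metric dialects (SSIM window, NMI bin count) affect absolute values;
  cross-study comparisons should pin the configuration.
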