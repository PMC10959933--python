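# Methods

This note records the models, parameter choices and numerical decisions
behind `fovecast`, and what the phantom-based validation does and does not
establish.

## Phantom model

A phantom cube samples a layered retina on the native OCT grid
(default 256 slices × 992 axial × 512 lateral pixels over a 6 × 6 mm²
field, 2.6 µm axial pitch; tests and the smoke study use a 32 × 192 × 96
grid over 3 mm at 5.2 µm). Ten bands are rendered inner-to-outer — NFL,
GCL, IPL, INL, OPL, ONL, ELM, EZ, RPE, choroid — with fixed alternating
gray levels so each band is distinguishable from its neighbours; the RPE is
the brightest (250/255), as in real scans, because it anchors
registration. Default band thicknesses sum to a 280 µm neurosensory stack,
a realistic parafoveal value. The EZ band renders with a dark myoid zone in
its upper 40 % and the bright ellipsoid line below, reproducing the
dark-bright-dark-bright lamination of the outer retina that makes
ELM-vs-EZ continuity decidable; without that separation the two bright
lines would be anatomically fused, which real OCT does not show.

Geometry: the RPE floor is a shallow bowl (up to 40 µm deeper at the field
edge); the foveal pit thins the inner five layers by a Gaussian radial
profile (default depth 110 µm, FWHM 1.2 mm). The preoperative crater
multiplies all neurosensory thicknesses by a smoothstep radial factor that
is exactly zero inside the hole radius — so the zero-retina area grows
strictly with hole diameter. Postoperative ELM/EZ defects replace the band
intensity by outer-nuclear gray inside a lateral diameter, leaving geometry
untouched. Noise is additive Gaussian clipped to [0, 255]; OCT speckle
statistics, vascular shadowing and other pathologies are intentionally out
of scope, so a pass on phantoms shows algorithmic correctness, not clinical
robustness.

Misalignment is part of the phantom truth: the preoperative volume is
rendered on a grid extended past the nominal field by the maximum
displacement the rigid transform can produce, resampled trilinearly
through the transform, and cropped back. The extension matters: resampling
an already-cropped render drags zero-filled borders into the field and
corrupts the registration benchmark with an artifact no real acquisition
has.

Cohort sampling draws hole diameters from N(450, 215²) µm truncated at
100 µm (a realistic surgical distribution), jitters layer thicknesses
±10 % and pit depth ±20 %, assigns residual ELM defects to ~27 % and EZ
defects to ~33 % of cases (the approximate prevalence of incomplete
outer-band recovery), and samples rigid misalignments uniformly within
configurable bounds.

## Registration

The RPE height is the axial argmax of the Gaussian-smoothed A-scan
(σ ≈ 1 px) inside a search band spanning 20–92 % of the axial extent, with
parabolic sub-pixel refinement; the band is generous at the top so ±150 µm
misalignments cannot push the surface out of it. The height grid is 3 × 3
median filtered and grid points more than 5 robust standard deviations
(1.4826·MAD, floored at half a pixel so clean data are never
self-rejected) from their local median are invalidated, as are columns
whose peak response is below 30/255.

Fitting is closed-form orthogonal Procrustes (Kabsch) on grid-corresponded
point clouds in physical µm, centred on the cube centre. Correspondence by
(slice, column) index is exact for the axial component; the in-plane
components are constrained only through the surface shape (bowl + pit), so
recovery of a transform from two *extracted* surfaces is approximate, while
recovery from an analytically transformed cloud is exact to machine
precision — the test suite checks both, and the clinically relevant
endpoint is the post-registration RPE residual, which stays below one
axial pixel across sampled misalignments up to 5° and 150 µm.

Resampling is trilinear in physical coordinates with zero fill, using
border-interpolating out-of-field handling (`grid-constant`): hard
zero-substitution at the first out-of-range coordinate would corrupt
border voxels under sub-pixel transforms. Volumes are processed in slice
blocks to bound memory.

## Preprocessing

The 448 → 224 Lanczos downscale follows the stated protocol; rotations and
shifts in augmentation use bilinear resampling with zero fill, which is
sufficient for augmentation fidelity. The postoperative member of a pair
reuses the preoperative COM so the two members stay in spatial
correspondence, and validation/test splits are never augmented
(25 × 200 = 5,000 validation pairs confirms this bookkeeping).

Condition bands: the per-case histogram over the 200-slice fovea-centred
window is fixed at 43/42/43/72 slices for conditions 0/1/2/3. With the
window centre at position 99.5, the implemented inclusive position ranges
are 0 = [78, 120], 1 = [57, 77] ∪ [121, 141], 2 = [36, 56] ∪ [142, 163],
3 = [0, 35] ∪ [164, 199]; odd band sizes force a one-slice asymmetry,
placed on the high-index (nasal, by this package's orientation convention)
side. The edges are exposed in `preprocess.CONDITION_BAND_EDGES`; reduced
windows scale the canonical table proportionally. Sampling weights are
1/count(condition), giving a uniform expected condition distribution under
weighted draws.

Orientation convention: column 0 is the temporal side for right eyes.

## Conditional VAE

Fixed by design: four convolution blocks (k3/s1/p1, channels C, 2C, 4C,
8C, batch-norm + leaky-ReLU + dropout + 2×2 max-pool), five fully
connected layers per side — implemented as three shared hidden layers plus
the parallel µ/log-variance heads on the encoder, and five stacked layers
on the decoder — condition one-hot concatenated at the first encoder FC
layer and to z at the decoder input (a conditional decoder must see the
condition), nearest-neighbour 2× unpooling, sigmoid output, 600-epoch
budget with the reconstruction family switching at epoch 400, KLD warm-up,
early stopping, and best-validation-epoch weight selection.

Chosen here (unspecified upstream): Adam (lr 1e-4 full-scale, 1e-3 for
smoke runs), batch 16, dropout 0.1, leaky slope 0.2, latent dimension 256
(32 in smoke runs), base channels 32 (8), linear warm-up over 50 epochs
(β(0) = 0, β(E_w) = 1), patience 30, global gradient-norm clipping at 5,
and a [−8, 8] clamp on the log-variance head — without the clamp the KLD
term can overflow in the first epochs. BCE is dropped when the perceptual
family takes over (configurable), and batch normalisation mirrors into the
decoder except at the output layer. Validation uses evaluation mode with
z = µ, so the recorded validation loss is deterministic, and it is
evaluated at β = 1 regardless of the warm-up stage — otherwise the early
low-β epochs would trivially minimise the recorded loss and best-epoch
selection would always pick a barely trained model. Note that the loss
scale changes at the family switch, so best-epoch selection after the
switch compares losses within the perceptual family. Epochs are numbered from 0; "epoch ≤ switch" uses
the BCE + MS-SSIM family.

MS-SSIM uses the standard 5-scale weights, an 11-pixel Gaussian window
(σ = 1.5) applied as separable valid-mode correlations, and drops to as
many dyadic scales as fit the image (weights renormalised) — three scales
at 64 px. Component maps are clamped below at 1e-4 before the weighted
geometric product, the usual guard against negative contrast terms. The
perceptual loss is a frozen random-convolution feature distance (three
3 × 3 stages, widths 8/16/16, leaky-ReLU, 2× average pooling, He-scaled
Gaussian kernels from a fixed seed): a deterministic, self-contained
multi-layer feature space. It is pluggable — any callable
`(x, y) -> Tensor` can replace it.

The autodiff engine is float64 throughout; every operator's gradient is
validated against central finite differences in the test suite.

## Metrics

Segmentation: ILM = first sustained (2 px) crossing of a 0.10 threshold on
the smoothed column; RPE = brightest smoothed response below; curves
median-smoothed over 7 columns; a supplied-curves hook bypasses detection
(the analogue of manual boundary correction). Confusion counts take GT as
the reference; undefined F1 is reported as 0 with a flag. Thickness
windows convert µm to columns with half-up rounding and inclusive bounds;
FH is read at the supplied fovea column (not the minimum-thickness
column). Bland–Altman uses percentage differences
d = 100(a−g)/((a+g)/2), bias ± 1.96 · sample SD, and the ±30 % acceptance
rule on both limits.

Band continuity: within ±1000 µm of the foveola, each column's expected
depth stratum — 36–65 µm above the RPE response for the ELM, 20–33 µm for
the EZ line, rounded inward so the stratum never clips the RPE band —
must contain a response ≥ 0.5; the longest failure run in µm is the gap,
and the band is restored iff the gap is at most the 50 µm tolerance (a
configurable stand-in for the human grader's indifference to hairline
breaks; one lateral pixel at native sampling is ~12 µm). The ten-point
layer-visibility score is a phantom-only proxy for human image-quality
grading: one point per band that both contrasts with its axial neighbours
(> 0.05) and renders within 0.25 of its designed gray level — the second
clause makes an erased band lose its point even though it still contrasts
with its neighbours.

## Problem sizes

Unit tests run on 32 × 192 × 96 phantoms at 5.2 µm axial pitch (the whole
retina then fits a 128-pixel crop downscaled to 64). The smoke study used
by the acceptance script trains on 20 cases (14/3/3 split, 6 fovea-centred
slices per case, six-fold augmentation → 504 training pairs) for 25
epochs at 64 × 64 with C = 8 and d = 32, drawing 192 weighted samples per
epoch; these sizes are the package's chosen desk-scale study conditions.
One test renders a full native-geometry cube to pin the 256 × 992 × 512
contract.

## Known limitations

- Phantoms are piecewise-constant with Gaussian noise; no speckle, no
  shadowing, no real anatomical variability. Metrics tuned here (strata,
  thresholds) would need re-tuning for clinical scans.
- Grid-corresponded surface fitting observes in-plane motion only through
  surface curvature; strongly flat retinas would make those components
  poorly determined.
- The smoke-scale VAE demonstrates learning (validation-loss decrease,
  trained-vs-untrained separation), not clinical-grade synthesis; the
  architecture scales to 224 × 224 but full-scale training on a CPU is
  impractical.
- The condition-band edges reproduce the published per-condition totals
  exactly, but the side assignment of the one-slice asymmetries is a
  convention, not an identifiable fact.
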