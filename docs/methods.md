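# Methods

This note records the models implemented in `sonotkv`, the parameter choices
that matter, the numerical conventions, and what the phantom-based tests do
and do not demonstrate about clinical data.

## Phantom model

A phantom acquisition is a tracked freehand sweep over one kidney,
parameterized by `PhantomSpec`:

- **Kidney geometry.** An ellipsoid with semi-axes *(a, b, c)* mm (depth,
  lateral, sweep), Euler-rotated and offset from the sector's mid-depth
  point. Cysts are spheres given in the kidney's local frame so they travel
  with the kidney under orientation jitter. Sampled cysts are constrained to
  lie strictly inside the ellipsoid (conservative criterion
  ‖q/axes‖ + r/min(axes) ≤ 0.95), so the analytic kidney volume is exactly
  4/3·π·abc. For hand-built specs with protruding cysts the extra union
  volume is evaluated by deterministic grid quadrature at 0.25 mm — a
  sphere–ellipsoid intersection has no closed form.
- **Field of view.** A 2D circular sector (apex near the frame top, angular
  width ≈ 52–80°, depth ≈ 70–92 % of the frame) replicated along the sweep
  axis. Voxels outside the sector are exactly zero. The first and last ~8 %
  of frames are blank (probe not acquiring), which is what makes the
  blank-frame filter meaningful on phantoms.
- **Echo model.** A piecewise tissue template (background 0.50, kidney
  parenchyma 0.28, anechoic cysts 0.05, bright capsule rim 0.88 in a shell of
  the scaled ellipsoid distance 0.90–1.10), Gaussian-smoothed, multiplied by
  depth attenuation `exp(−μ·depth)` with μ = 0.004 /mm and by the per-patient
  gain, then corrupted by first-order multiplicative speckle
  `1 + s·(Rayleigh(mean 1) − 1)` and quantized to 8 bits. This is a
  first-order B-mode approximation intended to stress segmentation, not a
  wave-propagation simulation.
- **Acquisition variability.** Four scenarios mirror common clinical
  challenges: `centered`, `small_fov` (narrow/shallow sector), `low_contrast`
  (gain at the low end of the 0.54–0.68 span, elevated speckle), and
  `oversized` (kidney long axis exceeding the sector depth, so the ground
  truth is clipped by the field of view). Scan triples re-render the same
  kidney with orientation (±6°), gain (±0.02) and probe-placement (±3 mm)
  jitter; the speckle generator is seeded from the jittered geometry so zero
  jitter reproduces bit-identical sweeps.
- **Grids.** Desk scale: 128² in-plane, 48 frames, (1.2, 1.2, 2.2) mm
  spacing — kidneys of roughly 100–650 mL, CPU-sized. Full scale: 256²,
  320 frames, (0.7, 0.7, 0.42) mm, matching clinical stack geometry. The
  mask's voxelized volume converges to the analytic volume as spacing
  shrinks (verified at 2, 1, 0.5 mm).

The phantom does **not** emulate: tracker alignment residuals between frames
(slices are perfectly aligned), shadowing and reverberation artifacts,
adjacent organs (liver/spleen) that cause the hardest clinical boundary
errors, or non-ellipsoidal kidney deformation. Passing phantom tests
therefore demonstrates that the pipeline's machinery is correct and that the
model can learn speckle-corrupted boundary cues — not that clinical-grade
accuracy is achieved on patients.

## Preprocessing geometry

Two geometries are kept deliberately distinct:

- the **storage/analysis geometry** (default 320², desk scale 128²), reached
  by centred zero-padding or centred cropping. A paired mask shifts the crop
  window so no kidney voxel is ever discarded; if the kidney cannot fit, the
  operation is rejected. All volumetry happens here, avoiding
  resolution-dependent bias from the model geometry.
- the **model geometry** (default 256², desk 64²), reached by bilinear
  resampling (masks nearest-neighbour), with the exact inverse resampling
  applied to predictions before volumetry. Resampling rather than cropping
  is used because a 320→256 crop could truncate large kidneys.

The blank-frame filter runs after standardization and keeps frame *i* iff
its non-zero-pixel fraction is ≥ 0.20, inclusive at the boundary. It is
applied to images only, is idempotent, and is monotone in the threshold.
Slabs take frames (*z*−1, *z*, *z*+1) with edge clamping at the sweep ends —
the 2.5D convention that gives a 2D network through-plane context.

## Augmentation

Each training pair expands to `multiplier` pairs (default 3 = original + 2
warped copies): a rotation drawn uniformly from ±15° composed with an
elastic displacement field (coarse control grid of 32 px pitch, Gaussian
displacements of σ = 4 px at 256², bicubic-upsampled). Image and mask share
the warp; masks stay strictly binary. Defaults keep deformations visible but
anatomy-preserving — augmented mask areas stay within 20 % of the original.
Horizontal flip and additive Gaussian noise are implemented but off by
default: flipping destroys left/right anatomical cues and noise adds little
on speckle-corrupted inputs.

## Segmentation network

Full-scale architecture: 6 resolution levels, one conv–batch-norm–ReLU block
per level, encoder filters 32, 64, 128, 256, 512, 1024, kernel schedule
[7, 7, 5, 5, 3, 3] down and mirrored back up, 2×2 max pooling, learned 2×2
stride-2 up-convolutions with skip concatenation, and a 1×1 sigmoid head:
19.15 M trainable parameters. The classic two-convs-per-level U-Net with
this filter/kernel schedule would exceed 28 M; one block per level is what
lands the architecture at the intended ≈18 M size. The slab size must be
divisible by 2^(levels−1).

Training choices (unspecified details fixed as): Adam optimizer (the
configured learning rate of 10⁻⁶ at full scale indicates a fine-tuning
regime on pretrained weights); batch size 8; zero-padded convolutions; batch
normalization per level; per-slab intensity scaling by 1/255; binarization
threshold 0.5 (exposed in config); best-validation-Dice checkpoint retained.
Loss is soft Dice with ε = 10⁻⁶ smoothing, computed over the batch.
Training rejects any patient identifier appearing in both the train and
validation partitions. A `pretrained_weights_path` hook loads a same-
architecture checkpoint before training (transfer learning); no pretrained
weights ship with the package.

Desk-scale configuration (`desk_unet_config`): 4 levels, base 8 filters
(8→64), 64-px slabs, 3×3 kernels, ≈60 k parameters, Adam at 3·10⁻³ for 12
epochs. The learning rate was chosen to pass the single-slab overfit smoke
test (Dice ≥ 0.95 within 200 epochs); since no pretrained ultrasound weights
exist, the fine-tuning rate of 10⁻⁶ would be inappropriate from random
initialization. The engine is numpy throughout: im2col convolution forward,
explicit col2im backward, einsum transposed convolution, argmax-routed
pooling gradients. Everything is deterministic under the configured seed.

## Evaluation conventions

- **FN** is the false-negative *rate* fn/(tp+fn) = 1 − sensitivity.
- **HD-95** defaults to the pooled variant: the 95th percentile of the union
  of both directed boundary-distance sets, boundary = foreground voxels with
  a background face-neighbour (array edges count as background). A
  `directed_mean` variant (mean of the two directed 95th percentiles) is
  available behind a flag. Units are voxels unless spacing is passed —
  reported pixel values are only comparable across identical grids.
- **Background-dominated metrics** (MCC, AUC) are computed over the
  standardized frame domain restricted to the kept (non-blank) frames;
  otherwise padded background swamps them and the numbers depend on padding.
- **Division-by-zero conventions**, flagged rather than silent: two empty
  masks → DSC/Jaccard/VS = 1 with `empty_masks`; fn-rate undefined when the
  reference is empty; MCC = 0 when its denominator vanishes; AUC undefined
  for a single-class reference; HD-95 undefined for an empty mask; an
  all-zero confusion table is rejected outright.
- **Slice-decile profile**: the reference kidney's slice extent [first, last
  foreground frame] is split into 10 contiguous bins by
  `floor(10·(z − z_start)/extent_length)`; per-bin Dice is pooled
  (2Σtp/(2Σtp+Σfp+Σfn)) over the bin's frames, with a frame-averaged mode
  available. Pooling was chosen because it weights frames by kidney area
  rather than giving thin end slices equal votes.

Identities `jaccard = dsc/(2−dsc)` and `vs ≥ dsc` hold by construction and
are verified against brute-force oracles to 10⁻⁹.

## Agreement statistics

Percent differences d = 100·(m₁−m₂)/((m₁+m₂)/2) accommodate the order-of-
magnitude spread of kidney volumes. Bias = mean(d); limits of agreement =
bias ± 1.96·SD(d) with the n−1 sample SD; the bias CI uses the t
distribution at n−1 df (standard practice at cohort sizes of ~20–50), and
bias is significant iff 0 lies outside that CI. Pairs with non-positive
means are rejected. A minimum of 2 pairs is accepted (the t interval is
defined at 1 df); R² requires 3. Regression keeps a free intercept. All
percent quantities are invariant to common rescaling of both series.

## Severity classification

Classes 1A–1E are assigned by comparing htTKV = TKV/height against
boundaries `150·(1+r)^age` (mL/m, r = 1.5 / 3 / 4.5 / 6 %/yr), isolated in
`class_thresholds` so an alternative parameterization can be swapped in.
Bands are half-open [lower, upper): a value exactly on a boundary takes the
higher class — conservative toward risk, and an explicit rule matters
because interscan variability can sit patients directly on a boundary. Ages
≤ 15 y are outside the model's domain and flagged, not refused. Only
typical bilateral (Class 1) morphology is modelled; atypical Class 2 is out
of scope. Severity is non-decreasing in TKV at fixed age/height and
non-increasing in age at fixed htTKV (verified on a 10⁴-point grid).

## Cohort summaries

The packaged 22-patient reference table is stored verbatim; one internal
inconsistency is preserved deliberately (the oldest patient is 75 while the
prose summary of the source cohort states a maximum of 70), so the maximum
age is reported as computed. BMI bands as printed leave [24.9, 25) unmapped;
contiguous half-open bands [18.5, 25), [25, 30), [30, ∞) are used, which
reproduce all printed counts (5/11/6). Display rounding is decimal half-up
(ages to years, heights to 2 dp — the 1.675 m median reads 1.68); raw values
are retained internally.

## Desk-scale experiment

`run_phantom_experiment` is the end-to-end study analogue: 12 phantom
patients (two kidneys × three sweeps each, difficulty mix cycling through
all four scenarios), split 8/1/3 at the patient level by seeded permutation
(the patient-count ratio 15:2:5 rescaled by largest-remainder
apportionment), ≤ 480 training slabs subsampled evenly across the training
sweeps, the desk U-Net above, and the full downstream panel. Problem sizes
were chosen so the whole experiment runs in about two minutes on one CPU
while every pipeline stage is exercised at realistic signal-to-noise.
Augmentation is available in the experiment config but off by default (the
phantom fleet already spans the acquisition variability the augmenter
emulates); the augmenter is exercised by its own test suite.

## Known limitations

- The speckle model is first-order multiplicative noise; real B-mode texture
  is spatially correlated and depth-dependent.
- Phantom kidneys are ellipsoids with spherical cysts; real ADPKD kidneys
  are far more irregular, and the liver boundary problem (the dominant
  clinical failure mode) is absent.
- No tracker misalignment between frames is simulated.
- The numpy engine is CPU-bound: the full-scale 19 M-parameter network is
  buildable and serializable but not practically trainable here; all
  training claims are desk-scale.
- HD-95 in voxel units is grid-dependent; use spacing for physical units.
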