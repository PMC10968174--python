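# Methods

`parotidseg` implements a desk-scale version of an adaptive-radiotherapy
support workflow for the parotid glands: automatic delineation on the
planning CT (pCT) with an attention-gated 3D U-Net, and propagation of the
delineated masks to weekly cone-beam CTs (CBCT) by deformable registration,
so that the week-1 to week-5 gland-volume change can be quantified as a
replanning signal.

## Containers and geometry

Volumes are `(z, y, x)` arrays with spacing and origin in millimetres.
Masks carry labels 0 (background), 1 (left parotid), 2 (right parotid); all
evaluation is performed on the *united* mask (label > 0).  Only NIfTI with
axis-aligned direction cosines is read or written — anything else raises
rather than silently mangling geometry.

## Preprocessing

CT volumes are resampled to a common spacing, default (3.0, 0.87, 0.87) mm,
with linear interpolation for images and nearest-neighbour for masks, and
the output grid size per axis is `round(n * s_in / s_target)` (round half
up, minimum 1).  Intensities are clipped to the soft-tissue window
(−160, 240) HU and mapped linearly onto [0, 1].  The linear map (rather
than z-scoring) was chosen so that loss and optimizer scales stay
conventional and the normalized-air padding value is exactly 0.

## Segmentation network

A five-stage encoder–bottleneck–decoder with filter counts 16/32/64/128 and
a 256-filter bottleneck on a 96³ input window.  Each stage is two
(3-kernel convolution → batch norm → ReLU) blocks; downsampling is 2×2×2
max-pooling, upsampling a stride-2 transpose convolution.  Every skip
connection passes through an attention gate: 1-kernel projections of the
skip features x (average-pooled to the coarse grid) and the gating signal g
from one level deeper are summed, passed through ReLU, a second 1-kernel
convolution and a sigmoid, and the resulting coefficients are trilinearly
resampled to x's grid and multiplied onto x.  `inter_channels` defaults to
half of x's channels.  The final stage is a 1-kernel convolution to 3
classes with a per-voxel softmax.

The network, its backward pass, and Adam are implemented directly on numpy
(no deep-learning framework is available in the target environment).
Convolutions use a shift-and-GEMM formulation; gradients are verified
against finite differences in the test suite.

## Training

96³ patches are sampled with centres inside the mask with probability 0.8
and outside with 0.2, four patches per volume forming one Adam batch
(default learning rate 1e-4; the phantom overfit experiment in the
acceptance suite uses Adam's standard 1e-3 because its ~100×-smaller
network only sees 800 optimizer steps, within which 1e-4 measurably cannot
leave the all-background basin).  "Inside" means the centre voxel's label is > 0;
patches crossing the border are padded with 0 (normalized air).  The loss is
`CE + (1 − soft-DSC)` with unit weights; the soft Dice uses probabilities
with a 1e-5 smoothing term in numerator and denominator and averages over
the three classes.  Validation computes the united-mask DSC with full-volume
sliding-window inference every 10 epochs, and the best-validation-DSC state
is the returned checkpoint.

Three standard stabilizers supplement the base protocol, each adopted after
a measured failure mode: the final-layer bias is initialized to the log
class priors (≈95% background), without which the imbalanced cross-entropy
first collapses the network to all-background and costs ~50 epochs of
digging out; the global gradient norm is clipped at 1.0, which removes rare
catastrophic batches that showed up as transient validation-DSC collapses;
and after checkpoint selection the batch-norm running statistics are
re-estimated on the sliding-window tile distribution (training batches are
gland-centred patches, inference tiles are mostly background — the
mismatch cost ~0.3–0.5 DSC points).  Cross-validation folds are built per source
with a running fold offset, so per-source counts differ by at most one and
both sources appear in every fold (48 + 42 samples give five folds of 18).

## Inference and evaluation

Sliding-window inference tiles the volume with 50%-overlapping windows,
accumulates Gaussian-weighted class probabilities (σ = window/8), and takes
the per-voxel argmax with ties broken toward the lower label.  Metrics on
the united masks: DSC, precision, recall from confusion counts (DSC of two
empty masks is 1 by convention), and HD95 as the maximum of the two directed
95th-percentile surface distances, with surfaces defined by 6-connectivity
and distances measured in millimetres via a spacing-aware Euclidean distance
transform.  Cases where either surface is empty are excluded from the HD
aggregate and counted.

## Registration

Each pair is histogram-matched first (monotone quantile mapping of the
moving intensities onto the fixed ones; 256 quantile knots).  The affine
stage is rigid-then-affine mutual information maximization: intensities
clipped to the (0.005, 0.995) quantiles, a 4-level pyramid (shrink 8/4/2/1,
smoothing 3/2/1/0 voxels) with iteration schedules 50/50/25/10 (rigid) and
100/70/50/20 (affine), MI from a 32-bin joint histogram on a random 10%
(rigid) or 25% (affine) sample of fixed-image points, optimized by
regular-step gradient descent on scale-normalized parameters (rotations and
matrix increments scaled by the mean half-extent so one unit ≈ 1 mm of edge
displacement; step halved on gradient-direction reversal, stopping below
1e-6).  The finite-difference probe for the metric gradient is one
scale-normalized unit (≈1 mm): the binned MI surface is locally rough and
sub-voxel probes read mostly noise.

The deformable stage is symmetric-forces demons: the fixed/warped intensity
difference drives a per-voxel displacement update along the averaged
gradients, `u += diff·J / (|J|² + diff²)`, capped at 1 voxel.  Two
regularization modes exist, chosen per pipeline stage after measured
failure modes of each.  In *update* mode (fluid-like, used for
CBCT1→CBCT5 with σ=2 and 600 iterations) the σ smooths the per-iteration
update and the accumulated field receives only a light 0.5-voxel diffusion;
this is the mode that can actually recover deformations — smoothing the
accumulated field with the full σ attenuates the stored deformation every
iteration and plateaued at 1.35 voxels mean endpoint error on a known
3-voxel sinusoidal field where the fluid variant reaches 0.07–0.6 voxels.
In *field* mode (classic diffusion demons, used for pCT→CBCT1 with σ=3)
the σ smooths the accumulated field; after the affine has aligned what is
the same anatomy, the expected residual deformation is near zero, and there
the fluid variant instead accumulates noise-driven drift (on
independent-noise pairs the update magnitude `|diff||J|/(|J|²+diff²)` is
scale-invariant, so pure-noise regions emit ~0.3–0.5-voxel forces forever;
at σ=3 the resulting coherent random walk measurably eroded warped gland
masks by a third).  Both images are pre-smoothed by 1 voxel before the
force is computed, which raises the signal-to-noise ratio of the
low-contrast gland boundary on CBCT-like noise; intensities are normalized
to the fixed image's robust (0.005, 0.995) range first.  Fields are stored
in millimetres on the fixed grid, mapping fixed-space points into moving
space, and label warping composes field-then-affine with nearest-neighbour
interpolation so no new labels can appear.  The affine pyramid's shrink
factor is capped so its coarsest level keeps at least ~12 voxels per axis —
a 32×32-bin MI histogram is meaningless on a few hundred points.

## Replanning assessment

Masks travel pCT → CBCT1 (histogram match + affine + demons σ=3) and
CBCT1 → CBCT5 (σ=2, 600 iterations); gland volume is foreground voxel count
× voxel volume; the replanning signal is the signed percentage change
`100·(v5 − v1)/v1` with the week-1 denominator.  Agreement with reference
changes is scored by MAE, RMSE and Pearson correlation.

## Synthetic phantoms — what they do and do not establish

The phantom is a soft-tissue head ellipsoid (40 HU) with a 5 mm bone shell
(700 HU) in air (−1000 HU) and two gland ellipsoids at 55 HU — only 15 HU
above soft tissue, mimicking the low parotid contrast of real CT — plus
8 HU Gaussian noise.  CBCT simulation applies gain 0.92, a +120 HU shift, a
smooth ±4% multiplicative bias field and 15 HU noise, preserving the
tissue-mean ordering so histogram matching stays well-posed.  Known
deformations are analytic: translations, a bounded sinusoidal field
(invertible while `amp·2π/period < 1`), and a local isotropic gland shrink
whose deformed gland is exactly the ellipsoid scaled by s (true volume
s³·V); the shrink field eases back to identity by an ellipsoidal-radius
smoothstep and the ground-truth deformed mask is rasterized by thresholding
the linearly interpolated label indicator at 0.5, which keeps its volume
within ~2% of the analytic value (pure nearest-neighbour resampling of the
voxelized mask aliased up to 3.4%).

Green phantom tests establish that the architecture, loss, metrics,
optimizer and registration machinery behave correctly and that the
end-to-end pipeline can recover prescribed anatomical change under
CBCT-like degradation.  They do not establish clinical segmentation
accuracy: phantom glands are high-regularity ellipsoids without
neighbouring confusable soft-tissue structures, the cohort-scale published
accuracies require the original datasets and GPU-scale training, and CBCT
artifacts (scatter, rings, truncation) are not simulated.

## Numerical choices and degenerate inputs

Soft-Dice smoothing 1e-5; MI in natural-log units; NCC undefined (NaN) for
zero-variance inputs; HD95 undefined for empty surfaces (excluded and
counted); percentile by linear interpolation between order statistics;
volumes smaller than the inference window are zero-padded and cropped back;
constant moving images pass through histogram matching unchanged with a
warning; non-finite losses or fields abort with a diagnostic rather than
propagating NaNs.

## Known limitations

Single-threaded numpy training is orders of magnitude slower than a GPU
framework, so the package targets reduced network/window configurations for
experimentation.  The affine optimizer can drift by a few tenths of a
percent in scale on already-aligned pairs (sampled-MI noise), visible as a
small systematic volume bias in the propagation pipeline.  Volumetric-change
tracking is resolution-limited: when the week-to-week gland-boundary
displacement falls below roughly half a voxel at ~12–14 HU contrast under
CBCT-like noise, per-patient demons recovery becomes erratic (measured at
1.8 mm voxels; reliable again at 1.5 mm).  DICOM/RT-STRUCT input is out of
scope (NIfTI only).
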