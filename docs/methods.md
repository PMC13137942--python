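# Methods

`cspine` implements a three-stage pipeline for cervical-spine CT:
self-supervised encoder pretraining on bone-windowed volumes, multi-class
vertebral segmentation (background + C1–C7) with structural priors and
geometry-consistency regularization, and per-vertebra fracture
classification from standardized oriented ROIs. Everything is exercised
on procedurally generated phantoms, so the package is testable without
clinical data.

## Data model and conventions

Volumes are `(x, y, z)`-indexed arrays in Hounsfield units with strictly
positive per-axis spacing in mm; `z` increases cranio-caudally (toward
the feet), and a voxel's physical position is `origin + index * spacing`
(voxel-center convention, 0-based). Label volumes share the grid of
their CT and take values 0 (background) and 1–7 (C1–C7). DICOM series
are sorted by the z component of ImagePositionPatient (InstanceNumber as
fallback) and converted to HU with RescaleSlope/Intercept; oblique
acquisitions (ImageOrientationPatient off axis-aligned by more than
0.01) are rejected rather than silently reoriented, since gantry-tilted
geometry is out of scope. Resampling is trilinear for intensities and
nearest-neighbor for labels, with output shape
`round(shape * spacing / target)`.

## Stage 1 — bone-biased masked autoencoding

The CT channel is bone-windowed (WL 300, WW 1500 HU): intensities are
clipped to [−450, 1050] and mapped linearly to [0, 1]. Crops are
partitioned into non-overlapping cubic patches; each patch is flattened,
linearly projected to dimension `d`, and offset by a learnable 3-D
positional embedding. The embedding is trilinearly resized
(align-corners) whenever the token grid differs from the reference grid,
so one encoder serves crops, full volumes, and ROIs.

Masking is bone-biased: with `b_i` the fraction of voxels above the
400 HU bone threshold in patch `i`, exactly `round(ρ·N)` patches are
drawn without replacement with weight `w_i = 1 − η·b_i`. The target
ratio ρ defaults to 0.7. The bias-to-probability mapping is not pinned
down by the method description, so the package fixes successive weighted
sampling without replacement: it gives exact ratio control and a
strictly monotone bias (inclusion probability decreasing in `b_i` for
η > 0), both of which are tested against an exact subset-enumeration
oracle. η defaults to 0.5 and is configurable.

The encoder processes only visible tokens; a lightweight decoder (a
single learned mask token, two transformer blocks, and a linear patch
head) reconstructs all patches, and the loss is the mean squared L2
reconstruction error over masked patches only. Reconstruction targets
are the raw windowed intensities (no per-patch normalization).

## Stage 2 — structure-aware segmentation

The network input stacks three channels: the windowed CT; a
bone-likelihood map (HU in [100, 400] ramped linearly to [0, 1], σ = 1
voxel Gaussian smoothing, re-clipped — clipping after smoothing, a
choice the source description leaves open); and an edge map
(|Laplacian-of-Gaussian, σ = 1 voxel| of the windowed channel, min-max
normalized, with a constant input mapping to zeros). Both smoothing
operators use reflect padding to avoid artificial boundary edges. A body
mask (HU > −300, largest 26-connected component, filled) restricts the
boundary loss; the −300 HU threshold and 26-connectivity are package
choices where the source states only "thresholding and
largest-component selection".

The segmentation network is UNETR-style: the shared ViT encoder (depth
4) provides token-grid features from all four blocks; stride-2
transposed convolutions bring them to 1/4, 1/2 and full resolution; and
a convolutional stem on the raw three-channel input supplies the
full-resolution skip, as in standard UNETR. Every skip passes through an
additive attention gate (`q = θ_x*x + θ_g*g + b`,
`α = σ(ψᵀ ReLU(q))`, `x̂ = α ⊙ x`; gate interior width = half the skip
channels) before concatenation, and each scale is refined by a residual
double convolution with group normalization. The full-resolution
double-convolution uses 1×1×1 kernels to bound CPU memory; the input
stem carries the high-frequency detail instead. Without that stem the
desk-scale decoder cannot resolve vertebra boundaries (foreground Dice
plateaus near 0.83 in the single-phantom overfit check; above 0.95 with
it).

The objective is
`Σ_c w_c (1 − Dice_c)^γ + α·L_WCE + β·L_boundary + λ_ord·L_ord + λ_ovl·L_ovl`
with soft (probabilistic) Dice, ε = 1e-5 smoothing, and cross-entropy
probabilities clipped at 1e-7. Defaults (`w_c = 1`, `γ = 1`, `α = 1`,
`β = 0.5`, `λ_ord = 0.1`, `λ_ovl = 0.1`, margin 1 mm) keep the
appearance terms dominant; none of these weights is prescribed by the
source, and all are config-exposed. The boundary term is realized as the
mean squared difference — over body-mask voxels — between the
min-max-normalized gradient magnitude of the foreground probability
(central differences, voxel units; the normalizing min/max treated as
constants of the step) and the edge channel. The ordering term is a
hinge on soft centroids computed in physical mm (spacing-aware), summed
over adjacent level pairs and divided by 6; classes with probability
mass below 1e-6 are skipped. The overlap term is the voxel-mean of
`Σ_k p_k·p_{k+1}`.

Training samples crops centered near labeled voxels; with a pretrained
encoder the lowest ⌈depth/3⌉ transformer blocks stay frozen for the
first 20% of epochs, then unfreeze. Self-training accepts a pseudo-label
level only if its largest component reaches a vertebra-specific minimum
volume (defaults 500 mm³ for C1, 700 mm³ elsewhere — phantom-scaled) AND
its mean softmax probability reaches 0.8; accepted cases enter the
sampling mix with weight `confidence^temperature`, capped so pseudo mass
never exceeds labeled mass. Pseudo-labels are only generated on the
training split, and every decision is written to a JSON-lines provenance
log.

Post-processing keeps the largest 26-connected component per class;
eigenvector signs are fixed (nonnegative z component, x/y tie-breaks) so
oriented bounding boxes are deterministic. A missing level is a recorded
outcome (`None`), not an exception, so the classification stage can
report "not assessed".

## Stage 3 — vertebra-level classification

Each vertebra is cropped on a grid centered at its component centroid
and aligned with its principal axes, resampled to a fixed
32 × 32 × 32-voxel field of view at 1 mm isotropic spacing from the
bone-windowed channel (out-of-volume samples take the windowed-air value
0). The source fixes no ROI numbers; this FOV tightly frames a ~30 mm
vertebral body — an earlier 48 × 48 × 64 mm default was mostly
background on phantoms and diluted the defect signal.

The frozen Stage-1 encoder embeds each ROI and the final-block tokens
are mean-pooled to `z_k`. Because pooled LayerNorm features have tiny
variance (~5e-3), the classifier standardizes them per dimension with
training-set statistics before the head — without this the MLP barely
moves from initialization. A learnable 16-dimensional level embedding is
concatenated (`z'_k = z_k ‖ e_k`); an optional single message-passing
step `Z'' = ReLU(Â Z' W)` over the C1↔…↔C7 chain (Â the
degree-normalized adjacency with self-loops, W dimension-preserving) can
diffuse cues across levels. The step is *disabled by default*: the
source marks it optional without stating whether it was active, and on
phantom cohorts — where fracture labels are independent across levels —
the Â-mixing dilutes per-level evidence and costs discrimination. A
two-layer MLP head (`σ(W₂·ReLU(W₁·z″) + b₂)`, hidden width 32, dropout
0.2 in training only) produces per-level probabilities; training
minimizes binary cross-entropy over balanced mini-batches (fractured
instances oversampled to 1:1 within each batch), and the operating
threshold is the unique-probability midpoint (including the all-positive
point) maximizing validation F1, ties resolved toward the higher
threshold.

## Evaluation

Metrics follow the standard confusion-count definitions (accuracy,
precision, recall/sensitivity, F1, specificity, FN rate), voxel-level
Dice `2TP/(2TP+FP+FN)` and IoU `TP/(TP+FP+FN)` per class with unweighted
macro averages over C1–C7 (classes absent from both volumes excluded),
ROC/AUC by trapezoidal integration with tied scores grouped, and the PR
curve with the positive-prevalence baseline. Zero-denominator metrics
are reported as missing, never coerced. HD95 extracts boundary voxels
(face-adjacent background neighbor), measures nearest-neighbor distances
between boundary-voxel centers in mm in both directions, pools the two
directed sets, and takes the 95th percentile; pooling (rather than the
max of two directed percentiles) is a documented package choice.

Cross-validation is patient-wise, stratified by a greedy assignment
(most-fractured studies first, seeded tie-breaking) that sends each
study to the eligible fold least loaded on its fractured levels; fold
sizes differ by at most one. Threshold calibration and pseudo-labeling
never touch a fold's test split; classification results aggregate the
unseen test predictions of all folds.

## Numerical backbone

All networks run on a compact reverse-mode automatic-differentiation
engine over float32 numpy arrays (`cspine.autodiff`): dense algebra,
softmax, reductions, gather, 3-D convolution via im2col, and an exact
stride-2/kernel-2 transposed convolution. Every operator's gradient is
verified against central finite differences in the test suite, and
optimization uses Adam. Checkpoints are `.npz` parameter archives with a
JSON config header. Inference runs under a no-grad context, and
full-volume segmentation is tiled (64-voxel blocks) to bound attention
memory. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; fixed seeds reproduce losses bit-for-bit on
a given platform.

## The phantom generator

Phantoms emulate the data contract of a cervical-spine CT study: seven
cranio-caudally ordered vertebrae as ellipsoidal bodies (default radii
16 × 13 × 11 mm) with a ~2 mm cortical shell drawn at 900 ± 100 HU,
trabecular interiors at 250 ± 60 HU, a soft-tissue cylinder at
40 ± 20 HU, air at −1000 HU, and additive Gaussian noise (σ = 10 HU);
C1/C2 additionally carry a posterior torus for ring-like morphology. A
fracture is an angular cortical defect: a wedge (default 70–110°) of the
shell replaced by soft-tissue HU, plus a radially displaced cortical
fragment (1.5–3 mm). Cohorts jitter centers, radii and shell thickness
per subject and draw per-level fracture indicators i.i.d.
Bernoulli(prevalence); the study-scale defaults are 87 subjects → 609
vertebra instances at 14% prevalence for bookkeeping checks, and a
60-subject cohort at 0.3 prevalence for the classification smoke test.

What the phantoms do *not* model: realistic vertebral shape (processes,
facets, endplates), intensity inhomogeneity and beam hardening, vendor
and slice-thickness heterogeneity, degenerative change, or correlated
multi-level injury patterns. Passing tests therefore demonstrate that
the pipeline's machinery — windowing, priors, masking bias, losses,
geometry, calibration, bookkeeping — is implemented correctly and can
learn the structures it is pointed at; they say nothing about clinical
accuracy on real CT.

## Problem sizes used

The defaults are sized for a single CPU: pretraining uses 32³ crops
with 8³ patches (d = 64, depth 4, heads 4) — the study-scale settings
(96³ crops, 16³ patches, 1 × 1 × 2 mm spacing, masking ratio 0.7) are
expressible through the same APIs for the pretraining stage, while the
desk-scale segmentation decoder is fixed to 8³ patches (three 2×
upsamplings); the single-phantom segmentation check runs on a 64³ grid;
and the classification study uses 60 subjects × 7 ROIs of 32³ voxels
with 5-fold cross-validation. `scripts/acceptance.py` re-runs the
masking contract, the segmentation overfit check, and the full
classification study from scratch at these sizes.

## Known limitations

* The autodiff engine is single-threaded and eager; it is sized for the
  desk-scale networks here, not for GPU-scale training.
* The segmentation decoder requires all volume axes divisible by 8 and
  the encoder fixed at depth 4.
* Self-training improves nothing on phantoms whose labeled and
  unlabeled distributions coincide by construction; the machinery is
  tested for its contracts (filtering, mixing, provenance), not for a
  accuracy gain.
* Fracture subtype/severity grading, patient-level aggregation rules
  beyond max-over-levels, and saliency visualization are out of scope.
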