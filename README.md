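# cspine

Cervical-spine CT analysis in three stages: **bone-window masked
autoencoding** to pretrain a 3-D vision-transformer encoder without
labels, **structure-aware vertebral segmentation** (background + C1–C7)
with a gated-attention U-Net and geometry-consistency regularization,
and **vertebra-level fracture classification** from standardized
oriented-bounding-box ROIs with anatomical level embeddings.

The package is aimed at medical-image-analysis researchers who want a
fully inspectable, CPU-scale implementation of this pipeline: every
stage runs in minutes on procedurally generated cervical-spine phantoms
(HU-valued volumes with cortical shells above 400 HU, trabecular
interiors, soft tissue, air, and optional cortical-defect fractures),
so no clinical dataset is required to run, test, or extend it.

## The model

**Stage 1.** Volumes are bone-windowed,
`x_CT = (clip(I_HU, −450, 1050) + 450)/1500`, and split into
non-overlapping cubic patches that are linearly embedded with a
learnable 3-D positional embedding (trilinearly resized across
fields-of-view). A target fraction ρ = 0.7 of patches is masked, drawn
without replacement with weight `w_i = 1 − η·b_i`, where `b_i` is patch
*i*'s fraction of voxels above 400 HU — bone-rich patches are masked
less often, so the encoder observes cortical structure more frequently.
The encoder sees only visible tokens; a lightweight decoder reconstructs
the rest under `L_MAE = (1/|M|) Σ_{i∈M} ‖x_i − x̂_i‖²`.

**Stage 2.** A UNETR-style U-Net takes three channels — windowed CT,
bone-likelihood (HU ∈ [100, 400] ramped to [0, 1], σ = 1 Gaussian), and
an edge map (|LoG, σ = 1| min-max normalized) — with every skip filtered
by an additive attention gate
`α = σ(ψᵀ ReLU(θ_x∗x + θ_g∗g + b))`, `x̂ = α ⊙ x`. The objective adds
boundary alignment and two geometric regularizers to focal Dice and
weighted cross-entropy:

    L_seg = Σ_c w_c (1 − Dice_c)^γ + α·L_WCE + β·L_Boundary
            + λ_ord·L_ord + λ_ovl·L_ovl

where `L_ord` softly enforces cranio-caudal centroid ordering
`z_k < z_{k+1}` and `L_ovl` penalizes coincident mass of adjacent
labels. Morphology-consistent self-training (volume- and
confidence-filtered pseudo-masks, confidence-based sampling) is
available for semi-supervised training.

**Stage 3.** Per-vertebra ROIs are cropped from the oriented bounding
box (largest component → centroid, principal axes, extents), resampled
to a fixed field of view, and encoded by the frozen Stage-1 encoder;
the pooled feature is concatenated with a learnable level embedding
(`z'_k = z_k ‖ e_k`), optionally mixed across levels by one chain-graph
message-passing step `Z'' = ReLU(Â Z' W)` with
`Â = D^{−1/2}(A+I)D^{−1/2}`, and scored by a two-layer MLP under binary
cross-entropy with balanced mini-batches; the decision threshold is
calibrated to maximize validation F1.

All networks run on a small reverse-mode autodiff engine over numpy
(`cspine.autodiff`) — no deep-learning framework is required.

## Worked example

```python
import numpy as np
from cspine.phantom import generate_phantom, PhantomSpec
from cspine.preprocess import build_prior_stack
from cspine.pretrain import partition_patches, bone_fraction, sample_mask
from cspine.metrics import ConfusionCounts, classification_metrics

sample = generate_phantom(PhantomSpec(seed=7))
print("volume:", sample.ct.shape, "spacing:", sample.ct.spacing)

stack = build_prior_stack(sample.ct)
inside = sample.labels.labels > 0
print(f"bone-likelihood mean inside vertebrae: {stack.bone_map[inside].mean():.3f},"
      f" outside: {stack.bone_map[~inside].mean():.3f}")

grid, blocks = partition_patches(sample.ct.voxels[:, :, 16:144], 16)
b = bone_fraction(blocks)
rich, free = b >= np.percentile(b, 95), b == 0.0
hits = np.zeros(grid.n_patches)
for s in range(500):
    hits[sample_mask(b, ratio=0.7, eta=0.5, seed=s).masked] += 1
print(f"masked per draw: {len(sample_mask(b, 0.7, 0.5, 0).masked)} of {grid.n_patches} (70%)")
print(f"masking rate, bone-rich top 5%: {hits[rich].mean()/500:.3f}; bone-free: {hits[free].mean()/500:.3f}")

m = classification_metrics(ConfusionCounts(tp=67, fp=20, fn=18, tn=504))
print("operating point: " + ", ".join(f"{k}={v:.3f}" for k, v in m.items()))
```

prints

```
volume: (128, 128, 160) spacing: (1.0, 1.0, 2.0)
bone-likelihood mean inside vertebrae: 0.574, outside: 0.002
masked per draw: 358 of 512 (70%)
masking rate, bone-rich top 5%: 0.682; bone-free: 0.700
operating point: accuracy=0.938, precision=0.770, recall=0.788, f1=0.779, specificity=0.962, fn_rate=0.212
```

The phantom's bone-likelihood prior concentrates inside the vertebrae;
the sampler masks exactly 70% of patches while masking bone-rich
patches less often; and the confusion-count metrics reproduce a full
operating point (accuracy, precision, sensitivity, F1, specificity,
false-negative rate) from the four counts.

The staged pipeline is also scriptable from the shell:

```bash
cspine phantom   --config configs/tiny.yaml --workdir runs/demo
cspine pretrain  --config configs/tiny.yaml --workdir runs/demo
cspine segment   --config configs/tiny.yaml --workdir runs/demo
cspine classify  --config configs/tiny.yaml --workdir runs/demo
cspine evaluate  --config configs/tiny.yaml --workdir runs/demo
```

which leaves checkpoints, cross-validated predictions, ROC/PR point
tables, and a `metrics_report.json` under the working directory, each
stage recording a manifest (config hash, seed, input digests).

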