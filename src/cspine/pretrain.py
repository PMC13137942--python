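"""Stage 1: bone-window masked-autoencoder pretraining.

The windowed CT channel is partitioned into non-overlapping cubic
patches; a target fraction ρ of the patches (default 70%) is masked and
must be reconstructed from the visible ones. Masking is *bone-biased*:
patches are drawn without replacement with weight ``w_i = 1 − η·b_i``,
where ``b_i`` is the fraction of voxels above the 400 HU bone threshold,
so bone-rich patches are masked less often and the encoder observes
cortical structure more frequently while the overall masking ratio is
held exactly at ``round(ρ·N)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, as_tensor
from .ctio import CTVolume
from .networks import MAEModel, ViTConfig
from .preprocess import window_normalize

__all__ = [
    "PatchGrid",
    "MaskSample",
    "BONE_THRESHOLD_HU",
    "partition_patches",
    "reassemble_patches",
    "bone_fraction",
    "sample_mask",
    "mae_loss",
    "MAETrainConfig",
    "pretrain_loop",
]

BONE_THRESHOLD_HU = 400.0
DEFAULT_MASK_RATIO = 0.7
DEFAULT_BIAS = 0.5


@dataclass(frozen=True)
class PatchGrid:
    patch_size: int
    dims: tuple[int, int, int]  # patches per axis

    @property
    def n_patches(self) -> int:
        return int(np.prod(self.dims))


@dataclass(frozen=True)
class MaskSample:
    masked: np.ndarray        # sorted indices of masked patches
    visible: np.ndarray       # complement, sorted
    bone_fractions: np.ndarray
    ratio: float
    seed: int


def partition_patches(channel: np.ndarray, patch_size: int):
    """Split a (X, Y, Z) array into non-overlapping cubes.

    Returns ``(PatchGrid, blocks)`` with ``blocks`` of shape
    (N, p, p, p) in C order over the patch grid; every axis must be
    divisible by ``patch_size``.
    """
    arr = np.asarray(channel)
    if arr.ndim != 3:
        raise ValueError("expected a 3-D array")
    p = int(patch_size)
    if any(s % p for s in arr.shape):
        raise ValueError(f"shape {arr.shape} not divisible by patch size {p}")
    dims = tuple(s // p for s in arr.shape)
    blocks = arr.reshape(dims[0], p, dims[1], p, dims[2], p) \
        .transpose(0, 2, 4, 1, 3, 5).reshape((-1, p, p, p))
    return PatchGrid(p, dims), blocks


def reassemble_patches(grid: PatchGrid, blocks: np.ndarray) -> np.ndarray:
    """Inverse of :func:`partition_patches`."""
    p = grid.patch_size
    gx, gy, gz = grid.dims
    return np.asarray(blocks).reshape(gx, gy, gz, p, p, p) \
        .transpose(0, 3, 1, 4, 2, 5).reshape(gx * p, gy * p, gz * p)


def bone_fraction(ct_patch: np.ndarray) -> float | np.ndarray:
    """Fraction of voxels above the 400 HU bone threshold.

    Accepts one patch (p, p, p) → float, or a stack (N, p, p, p) →
    per-patch fractions.
    """
    arr = np.asarray(ct_patch, dtype=np.float32)
    if arr.ndim == 3:
        return float(np.mean(arr > BONE_THRESHOLD_HU))
    return (arr > BONE_THRESHOLD_HU).reshape(arr.shape[0], -1) \
        .mean(axis=1).astype(np.float64)


def sample_mask(bone_fractions: np.ndarray,
                ratio: float = DEFAULT_MASK_RATIO,
                eta: float = DEFAULT_BIAS,
                seed: int = 0) -> MaskSample:
    """Draw exactly ``round(ratio·N)`` masked patches without replacement
    with per-patch weight ``1 − eta·b_i``. ``eta = 0`` is uniform; for
    ``eta > 0`` bone-rich patches are strictly less likely to be masked.
    """
    b = np.asarray(bone_fractions, dtype=np.float64)
    n = b.size
    if not 0.0 < ratio < 1.0:
        raise ValueError("mask ratio must be in (0, 1)")
    if not 0.0 <= eta < 1.0:
        raise ValueError("bias strength eta must be in [0, 1)")
    m = int(round(ratio * n))
    if m == 0 or m == n:
        raise ValueError(f"ratio {ratio} on {n} patches leaves no visible "
                         "or no masked patch")
    w = 1.0 - eta * b
    rng = np.random.default_rng(seed)
    masked = np.sort(rng.choice(n, size=m, replace=False, p=w / w.sum()))
    visible = np.setdiff1d(np.arange(n), masked)
    return MaskSample(masked=masked, visible=visible, bone_fractions=b,
                      ratio=float(ratio), seed=int(seed))


def mae_loss(reconstructed, target, masked_idx):
    """Mean over masked patches of the squared L2 reconstruction error.

    ``reconstructed``/``target`` are (N, ·) per-patch vectors (or
    (N, p, p, p) blocks); visible patches contribute nothing. Accepts
    numpy (returns float) or Tensors (differentiable).
    """
    midx = np.asarray(masked_idx)
    if midx.size == 0:
        raise ValueError("masked index set must be nonempty")
    numpy_in = not isinstance(reconstructed, Tensor)
    rec = as_tensor(reconstructed)
    tgt = as_tensor(target)
    rec = rec.reshape(rec.shape[0], -1)[midx]
    tgt = tgt.reshape(tgt.shape[0], -1)[midx]
    diff = rec - tgt
    loss = (diff * diff).sum(axis=1).mean()
    return loss.item() if numpy_in else loss


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MAETrainConfig:
    crop: int = 32
    vit: ViTConfig = field(default_factory=lambda: ViTConfig(
        in_chans=1, patch_size=8, d=64, depth=4, heads=4, ref_grid=(4, 4, 4)))
    decoder_depth: int = 2
    mask_ratio: float = DEFAULT_MASK_RATIO
    bias_eta: float = DEFAULT_BIAS
    epochs: int = 30
    lr: float = 1e-3
    crops_per_volume: int = 4


def _biased_crop_origin(hu: np.ndarray, crop: int,
                        rng: np.random.Generator) -> tuple[int, int, int]:
    """Sample a crop origin with probability proportional to the crop's
    bone fraction (plus a floor so empty regions stay reachable)."""
    shape = hu.shape
    strides = [max(1, (s - crop) // 4) for s in shape]
    cands = []
    weights = []
    bone = hu > BONE_THRESHOLD_HU
    for ox in range(0, shape[0] - crop + 1, strides[0]):
        for oy in range(0, shape[1] - crop + 1, strides[1]):
            for oz in range(0, shape[2] - crop + 1, strides[2]):
                frac = bone[ox:ox + crop, oy:oy + crop, oz:oz + crop].mean()
                cands.append((ox, oy, oz))
                weights.append(frac + 0.01)
    w = np.asarray(weights)
    return cands[int(rng.choice(len(cands), p=w / w.sum()))]


def pretrain_loop(volumes: list[CTVolume],
                  config: MAETrainConfig | None = None,
                  seed: int = 0,
                  model: MAEModel | None = None):
    """Train a masked autoencoder on bone-windowed crops.

    Crop centers are sampled with a bias toward bone-rich regions.
    Returns ``(model, trace)`` where ``trace`` is the per-epoch mean
    masked reconstruction loss. Deterministic for fixed ``seed``.
    """
    cfg = config or MAETrainConfig()
    if not volumes:
        raise ValueError("need at least one volume")
    for v in volumes:
        if any(s < cfg.crop for s in v.shape):
            raise ValueError(f"crop {cfg.crop} exceeds volume shape {v.shape}")
    if cfg.crop % cfg.vit.patch_size:
        raise ValueError("crop must be divisible by patch size")
    rng = np.random.default_rng(seed)
    if model is None:
        model = MAEModel(cfg.vit, rng, decoder_depth=cfg.decoder_depth)
    opt = Adam(model.parameters(), lr=cfg.lr)
    trace: list[float] = []
    for epoch in range(cfg.epochs):
        losses = []
        for vol in volumes:
            for _ in range(cfg.crops_per_volume):
                ox, oy, oz = _biased_crop_origin(vol.voxels, cfg.crop, rng)
                hu = vol.voxels[ox:ox + cfg.crop, oy:oy + cfg.crop,
                                oz:oz + cfg.crop]
                xct = window_normalize(hu)
                grid, hu_blocks = partition_patches(hu, cfg.vit.patch_size)
                b = bone_fraction(hu_blocks)
                mask = sample_mask(b, cfg.mask_ratio, cfg.bias_eta,
                                   seed=int(rng.integers(0, 2**31 - 1)))
                tokens, tgrid = model.encoder.tokenize(xct[None])
                rec = model.reconstruct(tokens, tgrid, mask.visible)
                loss = mae_loss(rec, Tensor(tokens), mask.masked)
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(loss.item())
        trace.append(float(np.mean(losses)))
    return model, trace
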