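"""Composite Stage-2 segmentation objective.

``L = Σ_c w_c (1 − Dice_c)^γ + α·L_WCE + β·L_boundary
     + λ_ord·L_ord + λ_ovl·L_ovl``

* focal soft Dice and weighted cross-entropy measure appearance;
* the boundary term is the mean squared difference, over body voxels,
  between the min-max-normalized gradient magnitude of the foreground
  probability and the edge-enhancement channel;
* the ordering term softly enforces cranio-caudal centroid ordering
  ``z_k < z_{k+1}`` via a hinge with margin ``m`` (mm, spacing-aware
  centroids);
* the overlap term penalizes coincident probability mass of adjacent
  vertebra classes.

All functions accept plain numpy arrays (returning floats) or autodiff
Tensors (returning differentiable scalars); probabilities are expected
to be softmax outputs with the class axis first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, concat
from .ctio import N_LEVELS

__all__ = [
    "LossWeights",
    "onehot_encode",
    "focal_dice",
    "weighted_ce",
    "boundary_loss",
    "ordering_loss",
    "overlap_loss",
    "seg_loss",
]

_DICE_EPS = 1e-5
_PROB_CLIP = 1e-7
_MASS_EPS = 1e-6
N_CLASSES = N_LEVELS + 1


@dataclass(frozen=True)
class LossWeights:
    class_weights: tuple[float, ...] = tuple([1.0] * N_CLASSES)
    gamma: float = 1.0
    alpha: float = 1.0
    beta: float = 0.5
    lambda_ord: float = 0.1
    lambda_ovl: float = 0.1
    margin_mm: float = 1.0

    def __post_init__(self):
        vals = list(self.class_weights) + [self.alpha, self.beta,
                                           self.lambda_ord, self.lambda_ovl,
                                           self.margin_mm]
        if any(v < 0 for v in vals):
            raise ValueError("loss weights must be nonnegative")
        if self.gamma < 1.0:
            raise ValueError("focal exponent gamma must be >= 1")


def onehot_encode(labels: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(f"labels outside 0..{n_classes - 1}")
    oh = np.zeros((n_classes,) + labels.shape, dtype=np.float32)
    for c in range(n_classes):
        oh[c] = labels == c
    return oh


def _ret(x: Tensor, numpy_in: bool):
    return x.item() if numpy_in else x


def focal_dice(probs, onehot, class_weights=None, gamma: float = 1.0):
    """``Σ_c w_c (1 − Dice_c)^γ`` with soft Dice
    ``2Σpq / (Σp + Σq)`` smoothed by ε = 1e-5."""
    numpy_in = not isinstance(probs, Tensor)
    p = as_tensor(probs)
    q = as_tensor(onehot)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {q.shape}")
    nc = p.shape[0]
    w = np.ones(nc) if class_weights is None else np.asarray(class_weights)
    axes = tuple(range(1, p.ndim))
    inter = (p * q).sum(axis=axes)
    denom = p.sum(axis=axes) + q.sum(axis=axes)
    dice = (inter * 2.0 + _DICE_EPS) / (denom + _DICE_EPS)
    return _ret(((1.0 - dice) ** gamma * Tensor(w)).sum(), numpy_in)


def weighted_ce(probs, labels, class_weights=None):
    """Mean over voxels of ``−w_{y(v)} log p_{y(v)}(v)`` (probabilities
    clipped at 1e-7)."""
    numpy_in = not isinstance(probs, Tensor)
    p = as_tensor(probs)
    labels = np.asarray(labels)
    nc = p.shape[0]
    oh = onehot_encode(labels, nc)
    w = np.ones(nc) if class_weights is None else np.asarray(class_weights)
    wmap = (oh * w.reshape((nc,) + (1,) * labels.ndim)).sum(axis=0)
    logp = p.clip(_PROB_CLIP, 1.0).log()
    nll = -((logp * oh).sum(axis=0) * Tensor(wmap.astype(np.float32)))
    return _ret(nll.mean(), numpy_in)


def _grad_magnitude(p: Tensor) -> Tensor:
    """Central-difference gradient magnitude (edge-replicated), voxel units."""
    sq = None
    for ax in range(p.ndim):
        sl_lo = [slice(None)] * p.ndim
        sl_hi = [slice(None)] * p.ndim
        sl_lo[ax] = slice(0, 1)
        sl_hi[ax] = slice(p.shape[ax] - 1, p.shape[ax])
        padded = concat([p[tuple(sl_lo)], p, p[tuple(sl_hi)]], axis=ax)
        a = [slice(None)] * p.ndim
        b = [slice(None)] * p.ndim
        a[ax] = slice(2, None)
        b[ax] = slice(0, -2)
        d = (padded[tuple(a)] - padded[tuple(b)]) * 0.5
        sq = d * d if sq is None else sq + d * d
    return (sq + 1e-12).sqrt()


def boundary_loss(probs, edge_map, body_mask):
    """Mean over body voxels of ``(G − E)²`` with G the min-max-normalized
    foreground-probability gradient magnitude and E the edge channel.
    The normalizing min/max are treated as constants of the step."""
    numpy_in = not isinstance(probs, Tensor)
    p = as_tensor(probs)
    mask = np.asarray(body_mask, dtype=np.float32)
    if not mask.any():
        raise ValueError("body mask is empty")
    e = np.asarray(edge_map, dtype=np.float32)
    p_fg = 1.0 - p[0]
    g = _grad_magnitude(p_fg)
    lo, hi = float(g.data.min()), float(g.data.max())
    if hi - lo > 1e-12:
        g = (g - lo) * (1.0 / (hi - lo))
    else:
        g = g * 0.0
    diff = g - Tensor(e)
    return _ret((diff * diff * Tensor(mask)).sum() * (1.0 / mask.sum()),
                numpy_in)


def ordering_loss(probs, spacing, margin_mm: float = 1.0):
    """Hinge on soft centroids: ``Σ_{k=1..6} max(0, z_k − z_{k+1} + m)/6``.

    Soft centroid ``z_k = Σ_v z_mm(v)·p_k(v) / Σ_v p_k(v)`` in physical
    mm; classes with total mass below 1e-6 are skipped (their pair terms
    omitted).
    """
    numpy_in = not isinstance(probs, Tensor)
    p = as_tensor(probs)
    dz = float(spacing[2])
    nz = p.shape[3]
    zmm = (np.arange(nz, dtype=np.float32) * dz).reshape(1, 1, nz)
    centroids: dict[int, Tensor] = {}
    for k in range(1, N_LEVELS + 1):
        pk = p[k]
        mass = float(pk.data.sum())
        if mass < _MASS_EPS:
            continue
        centroids[k] = (pk * Tensor(zmm)).sum() / pk.sum()
    total = Tensor(0.0)
    for k in range(1, N_LEVELS):
        if k in centroids and k + 1 in centroids:
            total = total + (centroids[k] - centroids[k + 1]
                             + margin_mm).maximum(0.0)
    return _ret(total * (1.0 / (N_LEVELS - 1)), numpy_in)


def overlap_loss(probs):
    """Mean over voxels of ``Σ_{k=1..6} p_k·p_{k+1}`` (adjacent-level
    coincident probability mass)."""
    numpy_in = not isinstance(probs, Tensor)
    p = as_tensor(probs)
    acc = None
    for k in range(1, N_LEVELS):
        term = p[k] * p[k + 1]
        acc = term if acc is None else acc + term
    return _ret(acc.mean(), numpy_in)


def seg_loss(probs, labels, edge_map, body_mask,
             weights: LossWeights | None = None,
             spacing=(1.0, 1.0, 2.0)):
    """Weighted composite objective; returns ``(total, breakdown)`` where
    the breakdown maps component names to their unweighted values."""
    w = weights or LossWeights()
    numpy_in = not isinstance(probs, Tensor)
    p = as_tensor(probs)
    labels = np.asarray(labels)
    oh = onehot_encode(labels, p.shape[0])
    comp = {
        "focal_dice": focal_dice(p, oh, w.class_weights, w.gamma),
        "weighted_ce": weighted_ce(p, labels, w.class_weights),
        "boundary": boundary_loss(p, edge_map, body_mask),
        "ordering": ordering_loss(p, spacing, w.margin_mm),
        "overlap": overlap_loss(p),
    }
    if numpy_in:
        vals = {k: v.item() for k, v in comp.items()}
        total = vals["focal_dice"] + w.alpha * vals["weighted_ce"] \
            + w.beta * vals["boundary"] + w.lambda_ord * vals["ordering"] \
            + w.lambda_ovl * vals["overlap"]
        return float(total), vals
    total = comp["focal_dice"] + w.alpha * comp["weighted_ce"] \
        + w.beta * comp["boundary"] + w.lambda_ord * comp["ordering"] \
        + w.lambda_ovl * comp["overlap"]
    return total, comp
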