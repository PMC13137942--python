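"""Bone-window normalization and the auxiliary prior channels.

Three channels feed the segmentation network, in fixed order:

1. ``x_ct`` — the bone-window CT channel, clip(HU, −450, 1050) mapped
   linearly to [0, 1] (window level 300 HU, width 1500 HU);
2. ``bone_map`` — HU in [100, 400] mapped linearly to [0, 1], then
   smoothed by a 3-D Gaussian (σ = 1 voxel) and re-clipped;
3. ``edge_map`` — |Laplacian-of-Gaussian (σ = 1 voxel)| of ``x_ct``,
   min-max normalized to [0, 1].

A body mask (HU > −300, largest 26-connected component, holes filled)
restricts loss evaluation and removes non-body air.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .ctio import CTVolume

__all__ = [
    "PriorStack",
    "DegenerateInputError",
    "window_normalize",
    "bone_likelihood",
    "edge_map",
    "body_mask",
    "build_prior_stack",
    "WINDOW_LO",
    "WINDOW_HI",
    "BONE_HU_LO",
    "BONE_HU_HI",
]

WINDOW_LO, WINDOW_HI = -450.0, 1050.0   # bone window WL=300, WW=1500
BONE_HU_LO, BONE_HU_HI = 100.0, 400.0   # bone-likelihood ramp
BODY_HU_THRESHOLD = -300.0
_SIGMA = 1.0  # voxels, for both Gaussian smoothing and LoG


class DegenerateInputError(ValueError):
    """Raised when an input admits no meaningful result (e.g. all air)."""


@dataclass
class PriorStack:
    """Three-channel normalized input plus body mask."""

    x_ct: np.ndarray
    bone_map: np.ndarray
    edge_map: np.ndarray
    body_mask: np.ndarray
    spacing: tuple[float, float, float]

    def channels(self) -> np.ndarray:
        """Stacked (3, X, Y, Z) array in the fixed channel order."""
        return np.stack([self.x_ct, self.bone_map, self.edge_map], axis=0)


def _as_hu(volume) -> np.ndarray:
    if isinstance(volume, CTVolume):
        return volume.voxels
    return np.asarray(volume, dtype=np.float32)


def window_normalize(volume) -> np.ndarray:
    """clip(HU, −450, 1050) → [0, 1]; monotone and total."""
    hu = _as_hu(volume)
    return ((np.clip(hu, WINDOW_LO, WINDOW_HI) - WINDOW_LO)
            / (WINDOW_HI - WINDOW_LO)).astype(np.float32)


def bone_likelihood(volume) -> np.ndarray:
    """Piecewise-linear HU→[0,1] ramp over [100, 400], then σ=1 Gaussian
    smoothing (reflect boundaries), re-clipped to [0, 1]."""
    hu = _as_hu(volume)
    ramp = np.clip((hu - BONE_HU_LO) / (BONE_HU_HI - BONE_HU_LO), 0.0, 1.0)
    sm = ndimage.gaussian_filter(ramp.astype(np.float32), sigma=_SIGMA,
                                 mode="reflect")
    return np.clip(sm, 0.0, 1.0).astype(np.float32)


def edge_map(x_ct: np.ndarray) -> np.ndarray:
    """|LoG(σ=1)| of the windowed channel, min-max normalized.

    A constant input (zero response everywhere) maps to all zeros.
    """
    resp = np.abs(ndimage.gaussian_laplace(
        np.asarray(x_ct, dtype=np.float32), sigma=_SIGMA, mode="reflect"))
    lo, hi = float(resp.min()), float(resp.max())
    if hi - lo < 1e-12:
        return np.zeros_like(resp, dtype=np.float32)
    return ((resp - lo) / (hi - lo)).astype(np.float32)


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def body_mask(volume) -> np.ndarray:
    """Threshold HU > −300, keep the largest 26-connected component,
    fill holes. Raises :class:`DegenerateInputError` on an all-air volume."""
    hu = _as_hu(volume)
    fg = hu > BODY_HU_THRESHOLD
    if not fg.any():
        raise DegenerateInputError("volume contains no tissue above "
                                   f"{BODY_HU_THRESHOLD} HU")
    comp, n = ndimage.label(fg, structure=_STRUCT26)
    counts = np.bincount(comp.ravel())
    counts[0] = 0
    mask = comp == int(np.argmax(counts))
    return ndimage.binary_fill_holes(mask)


def build_prior_stack(volume: CTVolume) -> PriorStack:
    """Compute all three channels and the body mask for a volume at the
    working spacing."""
    x = window_normalize(volume)
    return PriorStack(
        x_ct=x,
        bone_map=bone_likelihood(volume),
        edge_map=edge_map(x),
        body_mask=body_mask(volume),
        spacing=volume.spacing,
    )
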