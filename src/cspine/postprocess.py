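"""Segmentation post-processing: component cleanup, per-vertebra
geometry, and standardized oriented-bounding-box ROIs.

For each vertebra class the largest 26-connected component is kept;
its voxel coordinates (physical mm) yield the centroid, the principal
axes (eigenvectors of the coordinate covariance, descending variance),
and oriented-bounding-box extents. ROIs for the classification stage
are resampled on a grid centered at the centroid and aligned with the
OBB axes, at a fixed shape and spacing, from the bone-windowed CT
channel (out-of-volume samples take the windowed-air value 0).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .ctio import CTVolume, N_LEVELS, SegLabelVolume, save_nifti
from .preprocess import window_normalize

__all__ = [
    "VertebraGeometry",
    "clean_labels",
    "vertebra_geometry",
    "extract_roi",
    "DEFAULT_ROI_SHAPE",
    "DEFAULT_ROI_SPACING",
    "write_roi_outputs",
]

DEFAULT_ROI_SHAPE = (32, 32, 32)
DEFAULT_ROI_SPACING = (1.0, 1.0, 1.0)
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class VertebraGeometry:
    level: int
    centroid: tuple[float, float, float]       # mm
    axes: np.ndarray                           # (3, 3) rows, orthonormal
    extents: tuple[float, float, float]        # mm per axis
    voxel_count: int
    mean_prob: float | None = None

    def __post_init__(self):
        self.axes = np.asarray(self.axes, dtype=np.float64)
        gram = self.axes @ self.axes.T
        if not np.allclose(gram, np.eye(3), atol=1e-6):
            raise ValueError("axes must be orthonormal")
        if any(e <= 0 for e in self.extents):
            raise ValueError("extents must be positive")


def clean_labels(pred: SegLabelVolume) -> SegLabelVolume:
    """Keep only the largest 26-connected component of each vertebra
    class; everything else becomes background. Idempotent."""
    out = np.zeros_like(pred.labels)
    for level in range(1, N_LEVELS + 1):
        mask = pred.labels == level
        if not mask.any():
            continue
        comp, n = ndimage.label(mask, structure=_STRUCT26)
        if n > 1:
            counts = np.bincount(comp.ravel())
            counts[0] = 0
            mask = comp == int(np.argmax(counts))
        out[mask] = level
    return SegLabelVolume(out, pred.spacing, pred.origin)


def _fix_signs(axes: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector signs: nonnegative z component, x as a
    tie-break when the z component vanishes."""
    fixed = axes.copy()
    for i in range(3):
        v = fixed[i]
        if v[2] < 0 or (abs(v[2]) < 1e-12 and (v[0] < 0 or
                        (abs(v[0]) < 1e-12 and v[1] < 0))):
            fixed[i] = -v
    return fixed


def vertebra_geometry(labels: SegLabelVolume, probs: np.ndarray | None,
                      level: int) -> VertebraGeometry | None:
    """Geometry of one (cleaned) vertebra component, or ``None`` when the
    level is absent from the volume (a recorded missing-level outcome,
    not an error)."""
    if not 1 <= level <= N_LEVELS:
        raise ValueError(f"level must be 1..{N_LEVELS}")
    idx = np.argwhere(labels.labels == level)
    if idx.size == 0:
        return None
    spacing = np.asarray(labels.spacing)
    coords = idx * spacing + np.asarray(labels.origin)
    centroid = coords.mean(axis=0)
    if len(coords) == 1:
        axes = np.eye(3)
    else:
        cov = np.cov(coords.T, bias=True)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        axes = _fix_signs(evecs[:, order].T)
    proj = (coords - centroid) @ axes.T
    margin = np.abs(axes) @ spacing  # one-voxel footprint per axis
    extents = proj.max(axis=0) - proj.min(axis=0) + margin
    mean_prob = None
    if probs is not None:
        pk = np.asarray(probs)[level]
        mean_prob = float(pk[tuple(idx.T)].mean())
    return VertebraGeometry(level=level,
                            centroid=tuple(float(c) for c in centroid),
                            axes=axes,
                            extents=tuple(float(e) for e in extents),
                            voxel_count=int(len(idx)),
                            mean_prob=mean_prob)


def extract_roi(ct: CTVolume, geom: VertebraGeometry,
                roi_shape=DEFAULT_ROI_SHAPE,
                roi_spacing=DEFAULT_ROI_SPACING) -> np.ndarray:
    """Bone-windowed ROI on an OBB-aligned grid centered at the centroid.

    Trilinear interpolation; samples outside the volume take the
    windowed-air value 0. Returns an array of ``roi_shape`` in [0, 1].
    """
    windowed = window_normalize(ct)
    shape = np.asarray(roi_shape)
    sp = np.asarray(roi_spacing, dtype=np.float64)
    offs = [np.arange(n) - (n - 1) / 2.0 for n in shape]
    ox, oy, oz = np.meshgrid(*[o * s for o, s in zip(offs, sp)],
                             indexing="ij")
    pts = (np.asarray(geom.centroid)[:, None]
           + geom.axes.T @ np.stack([ox.ravel(), oy.ravel(), oz.ravel()]))
    voxel_idx = (pts - np.asarray(ct.origin)[:, None]) \
        / np.asarray(ct.spacing)[:, None]
    roi = ndimage.map_coordinates(windowed, voxel_idx, order=1,
                                  mode="constant", cval=0.0)
    return roi.reshape(tuple(shape)).astype(np.float32)


def write_roi_outputs(ct: CTVolume, labels: SegLabelVolume,
                      probs: np.ndarray | None, out_dir,
                      roi_shape=DEFAULT_ROI_SHAPE,
                      roi_spacing=DEFAULT_ROI_SPACING) -> dict:
    """Write per-level ROI NIfTIs plus a geometry JSON sidecar; returns
    the sidecar dict (missing levels recorded as null)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cleaned = clean_labels(labels)
    sidecar = {}
    for level in range(1, N_LEVELS + 1):
        geom = vertebra_geometry(cleaned, probs, level)
        if geom is None:
            sidecar[f"C{level}"] = None
            continue
        roi = extract_roi(ct, geom, roi_shape, roi_spacing)
        save_nifti(CTVolume(roi, roi_spacing), out_dir / f"roi_C{level}.nii.gz")
        rec = asdict(geom)
        rec["axes"] = geom.axes.tolist()
        sidecar[f"C{level}"] = rec
    with open(out_dir / "geometry.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return sidecar
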