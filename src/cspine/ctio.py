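"""CT volume and label-volume containers plus DICOM/NIfTI I/O and resampling.

Conventions used throughout the package:

* voxel arrays are indexed ``(x, y, z)`` with ``z`` increasing caudally
  (toward the feet);
* voxel centers sit at ``origin + index * spacing`` (mm, 0-based indices);
* intensities are Hounsfield units; labels are integers ``0..7`` with
  label ``k >= 1`` meaning vertebra ``C_k``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from scipy import ndimage

__all__ = [
    "CTVolume",
    "SegLabelVolume",
    "FormatError",
    "load_dicom_series",
    "load_nifti",
    "save_nifti",
    "resample",
]

N_LEVELS = 7


class FormatError(ValueError):
    """Raised for malformed or unsupported input files."""


@dataclass
class CTVolume:
    """A 3-D CT volume in Hounsfield units on an axis-aligned grid."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.voxels.ndim != 3 or min(self.voxels.shape) == 0:
            raise ValueError("voxels must be a non-empty 3-D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class SegLabelVolume:
    """Integer label volume (0 = background, 1..7 = C1..C7)."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(self.labels, rounded):
                raise ValueError("labels must be integers")
            self.labels = rounded
        self.labels = self.labels.astype(np.int16)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.labels.ndim != 3 or min(self.labels.shape) == 0:
            raise ValueError("labels must be a non-empty 3-D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        lo, hi = int(self.labels.min()), int(self.labels.max())
        if lo < 0 or hi > N_LEVELS:
            raise ValueError(f"labels must lie in 0..{N_LEVELS}, got {lo}..{hi}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

_IOP_TOL = 0.01  # max deviation of ImageOrientationPatient from axis-aligned


def load_dicom_series(directory) -> CTVolume:
    """Load a single-frame CT series from ``directory``.

    Slices are sorted by the z component of ImagePositionPatient
    (InstanceNumber as fallback); stored values are converted to HU via
    RescaleSlope/RescaleIntercept. File-name ordering is irrelevant.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if len(datasets) < 2:
        raise FormatError(f"need >= 2 CT slices in {directory}")

    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) != 1:
        raise FormatError(f"inconsistent in-plane shapes: {sorted(shapes)}")

    def sort_key(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        if hasattr(ds, "InstanceNumber"):
            return float(ds.InstanceNumber)
        raise FormatError("slice lacks both ImagePositionPatient and "
                          "InstanceNumber")

    datasets.sort(key=sort_key)

    first = datasets[0]
    iop = getattr(first, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0])
    iop = np.asarray([float(v) for v in iop])
    if (np.abs(iop - np.array([1, 0, 0, 0, 1, 0])).max() > _IOP_TOL):
        raise FormatError("only axis-aligned axial series are supported "
                          f"(ImageOrientationPatient={list(iop)})")

    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float32) * slope + intercept)
    # pixel_array rows are y, columns are x -> transpose to (x, y)
    vol = np.stack([s.T for s in slices], axis=-1)

    row_sp, col_sp = (float(v) for v in first.PixelSpacing)
    if hasattr(first, "ImagePositionPatient"):
        zs = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
        dz = float(np.median(np.diff(zs)))
        if dz <= 0:
            raise FormatError("non-increasing slice positions after sort")
        origin = tuple(float(v) for v in first.ImagePositionPatient)
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
        origin = (0.0, 0.0, 0.0)
    return CTVolume(vol, spacing=(col_sp, row_sp, dz), origin=origin)


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def load_nifti(path, labels: bool = False) -> CTVolume | SegLabelVolume:
    """Load a NIfTI-1 volume; set ``labels=True`` for integer label masks."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3-D image, got {data.ndim}-D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    if labels:
        return SegLabelVolume(np.rint(data).astype(np.int16), spacing, origin)
    return CTVolume(data.astype(np.float32), spacing, origin)


def save_nifti(volume: CTVolume | SegLabelVolume, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(volume, SegLabelVolume):
        data = volume.labels.astype(np.int16)
    else:
        data = volume.voxels.astype(np.float32)
    img = nib.Nifti1Image(data, _affine(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample(volume: CTVolume | SegLabelVolume,
             target_spacing) -> CTVolume | SegLabelVolume:
    """Resample to ``target_spacing`` (mm): trilinear for intensities,
    nearest-neighbor for labels. Output shape is
    ``round(shape * spacing / target)``; identical spacing is an identity.
    """
    target = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target):
        raise ValueError("target spacing must be strictly positive")
    if np.allclose(target, volume.spacing):
        return volume
    is_labels = isinstance(volume, SegLabelVolume)
    data = volume.labels if is_labels else volume.voxels
    factors = np.array(volume.spacing) / np.array(target)
    out_shape = np.maximum(1, np.rint(np.array(data.shape) * factors)).astype(int)
    # voxel-center sample positions of the output grid in input index space
    coords = np.meshgrid(*[
        (np.arange(n) * target[a]) / volume.spacing[a]
        for a, n in enumerate(out_shape)], indexing="ij")
    coords = np.stack(coords)
    order = 0 if is_labels else 1
    res = ndimage.map_coordinates(
        data.astype(np.float32) if not is_labels else data,
        coords, order=order, mode="nearest")
    if is_labels:
        return SegLabelVolume(res.astype(np.int16), target, volume.origin)
    return CTVolume(res.astype(np.float32), target, volume.origin)
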