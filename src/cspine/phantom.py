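"""Procedural cervical-spine CT phantoms with ground-truth labels.

Each phantom is an HU-valued volume containing seven cranio-caudally
ordered "vertebrae": ellipsoidal bodies with a high-HU cortical shell
(well above the 400 HU bone threshold) and a medium-HU trabecular
interior, embedded in a soft-tissue cylinder surrounded by air. The two
most cranial levels additionally carry a posterior ring (torus) mimicking
the ringlike C1/C2 morphology. A fracture is modeled as an angular
cortical defect: a wedge of the shell replaced by soft-tissue-level HU,
optionally with a radially displaced cortical fragment.

The phantoms are deliberately simple — they exist so that windowing,
bone/edge priors, oriented-bounding-box geometry, masking bias,
segmentation and classification can all be exercised end to end without
any external dataset. They are not anatomically realistic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .ctio import CTVolume, N_LEVELS, SegLabelVolume, save_nifti

__all__ = [
    "FractureSpec",
    "VertebraSpec",
    "PhantomSpec",
    "PhantomSample",
    "generate_phantom",
    "generate_cohort",
    "save_sample",
    "save_cohort",
    "export_dicom",
]


@dataclass(frozen=True)
class FractureSpec:
    present: bool = False
    angular_width_deg: float = 90.0
    displacement_mm: float = 2.0
    angle_deg: float = 0.0  # azimuthal start of the defect wedge


@dataclass(frozen=True)
class VertebraSpec:
    center: tuple[float, float, float]  # mm
    radii: tuple[float, float, float] = (16.0, 13.0, 11.0)  # mm semi-axes
    has_ring: bool = False
    fracture: FractureSpec = field(default_factory=FractureSpec)


def _default_levels() -> tuple[VertebraSpec, ...]:
    levels = []
    for k in range(N_LEVELS):
        z = 60.0 + 34.0 * k
        levels.append(VertebraSpec(center=(64.0, 64.0, z), has_ring=k < 2))
    return tuple(levels)


def default_levels_for_grid(shape, spacing,
                            n_levels: int = N_LEVELS
                            ) -> tuple[VertebraSpec, ...]:
    """Place ``n_levels`` vertebrae centered in-plane and spread along
    the central 70% of the z extent, with radii capped so that jittered
    cohorts stay pairwise disjoint."""
    extent = [s * sp for s, sp in zip(shape, spacing)]
    cx, cy = extent[0] / 2.0, extent[1] / 2.0
    z0, z1 = 0.15 * extent[2], 0.85 * extent[2]
    dz = (z1 - z0) / max(n_levels - 1, 1)
    rz = min(11.0, 0.40 * dz)
    rx = min(16.0, 0.35 * min(cx, cy) * 2.0)
    ry = rx * 13.0 / 16.0
    return tuple(
        VertebraSpec(center=(cx, cy, z0 + dz * k), radii=(rx, ry, rz),
                     has_ring=k < 2)
        for k in range(n_levels))


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (128, 128, 160)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)
    levels: tuple[VertebraSpec, ...] = field(default_factory=_default_levels)
    shell_thickness_mm: float = 2.0
    cortical_hu: tuple[float, float] = (900.0, 100.0)   # mean, sd
    trabecular_hu: tuple[float, float] = (250.0, 60.0)
    soft_hu: tuple[float, float] = (40.0, 20.0)
    air_hu: float = -1000.0
    body_radius_mm: float = 48.0
    include_soft_tissue: bool = True
    ring_minor_radius_mm: float = 3.0
    noise_sd: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.cortical_hu[0] <= 400.0:
            raise ValueError("cortical mean HU must exceed the 400 HU "
                             "bone threshold")
        zs = [v.center[2] for v in self.levels]
        if not all(a < b for a, b in zip(zs, zs[1:])):
            raise ValueError("vertebra centers must strictly increase in z")
        for a, b in zip(self.levels, self.levels[1:]):
            gap = b.center[2] - a.center[2]
            if gap <= a.radii[2] + b.radii[2]:
                raise ValueError("adjacent vertebra bodies overlap in z")


@dataclass
class PhantomSample:
    ct: CTVolume
    labels: SegLabelVolume
    fracture_labels: np.ndarray  # (7,) 0/1
    spec: PhantomSpec


def _grids(spec: PhantomSpec):
    """Physical (mm) coordinates of voxel centers, sparse meshgrid."""
    ax = [np.arange(n, dtype=np.float32) * s
          for n, s in zip(spec.shape, spec.spacing)]
    return np.meshgrid(*ax, indexing="ij", sparse=True)


def _ellipsoid(x, y, z, center, radii) -> np.ndarray:
    cx, cy, cz = center
    rx, ry, rz = radii
    return (((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2
            + ((z - cz) / rz) ** 2) <= 1.0


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Rasterize one phantom. Deterministic for a fixed ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    x, y, z = _grids(spec)
    shape = spec.shape

    def draw(mean_sd):
        mean, sd = mean_sd
        if sd == 0:
            return np.full(shape, mean, dtype=np.float32)
        return rng.normal(mean, sd, size=shape).astype(np.float32)

    hu = np.full(shape, spec.air_hu, dtype=np.float32)
    if spec.include_soft_tissue:
        cx = spec.shape[0] * spec.spacing[0] / 2.0
        cy = spec.shape[1] * spec.spacing[1] / 2.0
        body = ((x - cx) ** 2 + (y - cy) ** 2) <= spec.body_radius_mm ** 2
        body = np.broadcast_to(body, shape)
        hu[body] = draw(spec.soft_hu)[body]

    labels = np.zeros(shape, dtype=np.int16)
    claim = np.zeros(shape, dtype=np.int8)  # overlap detector
    fracture_labels = np.zeros(N_LEVELS, dtype=np.int8)
    trab = draw(spec.trabecular_hu)
    cort = draw(spec.cortical_hu)
    soft = draw(spec.soft_hu)

    for k, vert in enumerate(spec.levels, start=1):
        outer = _ellipsoid(x, y, z, vert.center, vert.radii)
        inner_radii = tuple(max(r - spec.shell_thickness_mm, 0.5)
                            for r in vert.radii)
        inner = _ellipsoid(x, y, z, vert.center, inner_radii)
        shell = outer & ~inner
        level_mask = outer.copy()

        if vert.has_ring:
            cxk, cyk, czk = vert.center
            major = vert.radii[0] * 1.15
            rad = np.sqrt((x - cxk) ** 2 + (y - (cyk + vert.radii[1] * 0.7)) ** 2)
            torus = ((rad - major) ** 2 + (z - czk) ** 2) \
                <= spec.ring_minor_radius_mm ** 2
            torus = torus & ~outer
            shell = shell | torus
            level_mask = level_mask | torus

        hu[inner] = trab[inner]
        hu[shell] = cort[shell]

        frac = vert.fracture
        if frac.present:
            fracture_labels[k - 1] = 1
            phi = np.degrees(np.arctan2(y - vert.center[1], x - vert.center[0]))
            wedge = ((phi - frac.angle_deg) % 360.0) < frac.angular_width_deg
            defect = shell & np.broadcast_to(wedge, shape)
            hu[defect] = soft[defect]
            if frac.displacement_mm > 0:
                scale = 1.0 + frac.displacement_mm / min(vert.radii)
                disp_outer = _ellipsoid(x, y, z, vert.center,
                                        tuple(r * scale for r in vert.radii))
                disp_inner = _ellipsoid(
                    x, y, z, vert.center,
                    tuple(max(r * scale - spec.shell_thickness_mm, 0.5)
                          for r in vert.radii))
                fragment = disp_outer & ~disp_inner \
                    & np.broadcast_to(wedge, shape) & ~level_mask
                hu[fragment] = cort[fragment]

        labels[level_mask] = k
        claim[level_mask] += 1
        if claim.max() > 1:
            raise ValueError(f"vertebra {k} overlaps a previous level")

    if spec.noise_sd > 0:
        hu += rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)

    ct = CTVolume(hu, spec.spacing)
    lab = SegLabelVolume(labels, spec.spacing)
    return PhantomSample(ct=ct, labels=lab, fracture_labels=fracture_labels,
                         spec=spec)


def generate_cohort(n_subjects: int,
                    base_spec: PhantomSpec | None = None,
                    variability: float = 0.08,
                    prevalence: float = 0.14,
                    seed: int = 0) -> list[PhantomSample]:
    """Generate ``n_subjects`` phantoms with jittered geometry.

    Per-level fracture indicators are i.i.d. Bernoulli(``prevalence``);
    geometry (centers, radii, shell thickness) is jittered by the
    fractional ``variability``. Fully reproducible from ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    base = base_spec or PhantomSpec()
    master = np.random.default_rng(seed)
    samples = []
    for i in range(n_subjects):
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        levels = []
        for vert in base.levels:
            cx, cy, cz = vert.center
            jit = variability
            center = (cx + rng.normal(0, 3.0 * jit / 0.08),
                      cy + rng.normal(0, 3.0 * jit / 0.08),
                      cz + rng.uniform(-2.0, 2.0))
            radii = tuple(float(r * (1.0 + rng.uniform(-jit, jit)))
                          for r in vert.radii)
            frac = FractureSpec(
                present=bool(rng.random() < prevalence),
                angular_width_deg=rng.uniform(70.0, 110.0),
                displacement_mm=rng.uniform(1.5, 3.0),
                angle_deg=rng.uniform(0.0, 360.0))
            levels.append(replace(vert, center=center, radii=radii,
                                  fracture=frac))
        spec = replace(base, levels=tuple(levels),
                       shell_thickness_mm=base.shell_thickness_mm
                       * (1.0 + rng.uniform(-jit, jit)),
                       seed=int(rng.integers(0, 2**31 - 1)))
        samples.append(generate_phantom(spec))
    return samples


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def save_sample(sample: PhantomSample, directory, study_id: str) -> None:
    directory = Path(directory)
    save_nifti(sample.ct, directory / f"{study_id}_ct.nii.gz")
    save_nifti(sample.labels, directory / f"{study_id}_labels.nii.gz")


def save_cohort(samples: list[PhantomSample], directory,
                prefix: str = "phantom") -> list[str]:
    """Write NIfTI volumes/labels plus the fracture-label CSV
    (columns study_id, C1..C7). Returns the study ids."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ids = []
    rows = []
    for i, s in enumerate(samples):
        sid = f"{prefix}{i:04d}"
        save_sample(s, directory, sid)
        rows.append([sid] + [int(v) for v in s.fracture_labels])
        ids.append(sid)
    with open(directory / "fracture_labels.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["study_id"] + [f"C{k}" for k in range(1, N_LEVELS + 1)])
        w.writerows(rows)
    return ids


def export_dicom(ct: CTVolume, directory, shuffle_names_seed=None) -> None:
    """Write a CT volume as a single-frame axial DICOM series.

    Stored values are ``HU + 1024`` as uint16 with RescaleSlope 1 and
    RescaleIntercept −1024; HU outside [−1024, 64511] are clipped.
    ``shuffle_names_seed`` permutes file names (for loader-order tests).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nz = ct.shape[2]
    series_uid = generate_uid()
    order = np.arange(nz)
    if shuffle_names_seed is not None:
        np.random.default_rng(shuffle_names_seed).shuffle(order)
    for name_idx, k in enumerate(order):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.InstanceNumber = int(k) + 1
        ds.ImagePositionPatient = [ct.origin[0], ct.origin[1],
                                   ct.origin[2] + float(k) * ct.spacing[2]]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [ct.spacing[1], ct.spacing[0]]  # row, col
        ds.SliceThickness = ct.spacing[2]
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.Rows, ds.Columns = ct.shape[1], ct.shape[0]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        stored = np.clip(np.rint(ct.voxels[:, :, k].T) + 1024, 0, 65535)
        ds.PixelData = stored.astype(np.uint16).tobytes()
        ds.save_as(str(directory / f"slice_{name_idx:04d}.dcm"),
                   enforce_file_format=True)
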