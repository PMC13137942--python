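"""I/O and resampling: NIfTI/DICOM round trips, HU rescaling, and the
grid-resampling contracts."""

import numpy as np
import pytest

from cspine.ctio import (CTVolume, FormatError, SegLabelVolume,
                         load_dicom_series, load_nifti, resample, save_nifti)
from cspine.phantom import PhantomSpec, export_dicom, generate_phantom
from tests.conftest import small_levels


def _zero_noise_spec():
    return PhantomSpec(shape=(32, 32, 24), spacing=(2.0, 2.0, 3.0),
                       levels=small_levels(n=2, radii=(8, 7, 5), dz=16,
                                           z0=18),
                       cortical_hu=(900.0, 0.0), trabecular_hu=(250.0, 0.0),
                       soft_hu=(40.0, 0.0), noise_sd=0.0, seed=0)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

def test_volume_invariants_enforced():
    with pytest.raises(ValueError):
        CTVolume(np.zeros((4, 4, 4)), spacing=(1.0, 0.0, 1.0))
    with pytest.raises(ValueError):
        CTVolume(np.full((4, 4, 4), np.nan), spacing=(1, 1, 1))
    with pytest.raises(ValueError):
        SegLabelVolume(np.full((4, 4, 4), 9), spacing=(1, 1, 1))


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def test_nifti_roundtrip_volume_and_labels(tmp_path, small_sample):
    save_nifti(small_sample.ct, tmp_path / "ct.nii.gz")
    back = load_nifti(tmp_path / "ct.nii.gz")
    assert np.array_equal(back.voxels, small_sample.ct.voxels)
    assert np.allclose(back.spacing, small_sample.ct.spacing)

    save_nifti(small_sample.labels, tmp_path / "lab.nii.gz")
    lab = load_nifti(tmp_path / "lab.nii.gz", labels=True)
    assert np.array_equal(lab.labels, small_sample.labels.labels)


def test_nifti_anisotropic_spacing_preserved(tmp_path):
    vol = CTVolume(np.zeros((8, 8, 8), dtype=np.float32),
                   spacing=(0.5, 0.5, 3.0), origin=(1.0, -2.0, 5.0))
    save_nifti(vol, tmp_path / "v.nii.gz")
    back = load_nifti(tmp_path / "v.nii.gz")
    assert np.allclose(back.spacing, (0.5, 0.5, 3.0))
    assert np.allclose(back.origin, (1.0, -2.0, 5.0))


def test_nifti_rejects_non_3d(tmp_path):
    import nibabel as nib
    nib.save(nib.Nifti1Image(np.zeros((4, 4)), np.eye(4)),
             str(tmp_path / "flat.nii.gz"))
    with pytest.raises(FormatError):
        load_nifti(tmp_path / "flat.nii.gz")


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

def test_dicom_roundtrip_identity(tmp_path):
    sample = generate_phantom(_zero_noise_spec())
    export_dicom(sample.ct, tmp_path / "series")
    back = load_dicom_series(tmp_path / "series")
    assert np.array_equal(back.voxels, sample.ct.voxels)
    assert np.allclose(back.spacing, sample.ct.spacing)


def test_dicom_loader_invariant_to_file_order(tmp_path):
    sample = generate_phantom(_zero_noise_spec())
    export_dicom(sample.ct, tmp_path / "sorted")
    export_dicom(sample.ct, tmp_path / "shuffled", shuffle_names_seed=99)
    a = load_dicom_series(tmp_path / "sorted")
    b = load_dicom_series(tmp_path / "shuffled")
    assert np.array_equal(a.voxels, b.voxels)


def test_dicom_rescale_slope_intercept(tmp_path):
    """Stored value 762 with slope 2, intercept -1024 must read as 500 HU."""
    import pydicom
    sample = generate_phantom(_zero_noise_spec())
    export_dicom(sample.ct, tmp_path / "series")
    files = sorted((tmp_path / "series").iterdir())
    for f in files:
        ds = pydicom.dcmread(str(f))
        ds.RescaleSlope = 2.0
        ds.RescaleIntercept = -1024.0
        arr = np.full((int(ds.Rows), int(ds.Columns)), 762, dtype=np.uint16)
        ds.PixelData = arr.tobytes()
        ds.save_as(str(f), enforce_file_format=True)
    vol = load_dicom_series(tmp_path / "series")
    assert np.all(vol.voxels == 762 * 2 - 1024)
    assert float(vol.voxels[0, 0, 0]) == 500.0


def test_dicom_errors(tmp_path):
    import pydicom
    sample = generate_phantom(_zero_noise_spec())
    export_dicom(sample.ct, tmp_path / "bad")
    files = sorted((tmp_path / "bad").iterdir())
    ds = pydicom.dcmread(str(files[0]))
    ds.Rows = 8
    ds.Columns = 8
    ds.PixelData = np.zeros((8, 8), dtype=np.uint16).tobytes()
    ds.save_as(str(files[0]), enforce_file_format=True)
    with pytest.raises(FormatError):
        load_dicom_series(tmp_path / "bad")

    (tmp_path / "empty").mkdir()
    with pytest.raises(FormatError):
        load_dicom_series(tmp_path / "empty")


# ---------------------------------------------------------------------------
# resample
# ---------------------------------------------------------------------------

def test_resample_identity_and_constant(small_sample):
    same = resample(small_sample.ct, small_sample.ct.spacing)
    assert np.array_equal(same.voxels, small_sample.ct.voxels)

    const = CTVolume(np.full((10, 10, 10), 70.0, dtype=np.float32),
                     spacing=(2.0, 2.0, 2.0))
    half = resample(const, (1.0, 1.0, 1.0))
    assert half.shape == (20, 20, 20)
    assert np.allclose(half.voxels, 70.0, atol=1e-4)


def test_resample_linear_ramp_matches_analytic():
    """2 mm slices of a z-ramp resampled to 1 mm must follow the ramp."""
    nz = 16
    ramp = np.broadcast_to(np.arange(nz, dtype=np.float32) * 10.0,
                           (6, 6, nz)).copy()
    vol = CTVolume(ramp, spacing=(1.0, 1.0, 2.0))
    out = resample(vol, (1.0, 1.0, 1.0))
    assert out.shape == (6, 6, 32)
    z_mm = np.arange(out.shape[2]) * 1.0
    expected = np.clip(z_mm / 2.0, 0, nz - 1) * 10.0
    assert np.abs(out.voxels[3, 3, :] - expected).max() < 1e-3


def test_resample_labels_nearest_and_closed_set(small_sample):
    out = resample(small_sample.labels, (2.0, 2.0, 2.5))
    assert set(np.unique(out.labels)) <= set(np.unique(
        small_sample.labels.labels))
    assert out.labels.dtype == small_sample.labels.labels.dtype


def test_resample_rejects_bad_spacing(small_sample):
    with pytest.raises(ValueError):
        resample(small_sample.ct, (1.0, -1.0, 1.0))
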